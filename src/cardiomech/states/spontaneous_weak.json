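{
 "Vm": 0.0176903686442859,
 "CaSR": 0.10634336702336858,
 "Cai": 0.00021224863019043375,
 "d": 0.9787454202175543,
 "f1": 0.5258604204476554,
 "f2": 0.33042396558646636,
 "fCa": 0.9869283537093221,
 "h": 0.0003719155667049357,
 "j": 0.0003669966039485447,
 "m": 0.9999486876679733,
 "Xf": 0.0049599967677024055,
 "q": 0.004119023966816437,
 "r": 0.4424304147426932,
 "Nai": 9.226666662342542,
 "mL": 0.9999898878067894,
 "hL": 0.04591859811453851,
 "RyRa": 0.027325376442221796,
 "RyRo": 0.9954529244187117,
 "RyRc": 0.28382233018811936,
 "Xr1": 0.9912704347308603,
 "Xr2": 0.10723938917660654,
 "Xs": 0.1718011394961969,
 "N": 0.9977903515488286,
 "XBprer": 0.00034805883463188666,
 "XBpostr": 0.0009865133880586179,
 "xXBprer": -0.00016178547198571297,
 "xXBpostr": 0.0067474035939703875,
 "TRPNCaL": 0.11289111755311462,
 "TRPNCaH": 0.41186518795795934,
 "N_NoXB": 0.9991116151196545,
 "SL": 1.896082130251326,
 "intf": -1.6667762980096337e-05
}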
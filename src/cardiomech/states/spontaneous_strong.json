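{
 "Vm": -0.07517751051955102,
 "CaSR": 0.10280728302477983,
 "Cai": 2.588552054541317e-05,
 "d": 7.953657989567283e-05,
 "f1": 0.9097105363168747,
 "f2": 0.9999858317315389,
 "fCa": 0.9984620564100374,
 "h": 0.7830787740825874,
 "j": 0.1278012094702576,
 "m": 0.09816791335089084,
 "Xf": 0.04569850717998739,
 "q": 0.8454357151101551,
 "r": 0.005498652270995455,
 "Nai": 9.46295803077762,
 "mL": 0.0021476426542220936,
 "hL": 0.11071963480108117,
 "RyRa": 0.035801391192900205,
 "RyRo": 0.002519128732088331,
 "RyRc": 0.8201163862244123,
 "Xr1": 0.09510990763023418,
 "Xr2": 0.436200168852549,
 "Xs": 0.0308750043967396,
 "N": 0.9999770771685197,
 "XBprer": 3.6840016438405327e-06,
 "XBpostr": 1.8411491336885457e-05,
 "xXBprer": 6.21824752296321e-05,
 "xXBpostr": 0.007098034294140517,
 "TRPNCaL": 0.01627967663680482,
 "TRPNCaH": 0.1360163811434385,
 "N_NoXB": 0.9999992346242625,
 "SL": 1.8875291056182815,
 "intf": -3.570392730960107e-05
}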
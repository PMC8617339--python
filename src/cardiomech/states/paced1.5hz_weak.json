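{
 "Vm": -0.07606930590506218,
 "CaSR": 0.10726827681377915,
 "Cai": 2.590255498181083e-05,
 "d": 7.003993006407221e-05,
 "f1": 0.8784540073141625,
 "f2": 0.9999883908041985,
 "fCa": 0.9984595395567276,
 "h": 0.7971447509287773,
 "j": 0.11683299223730591,
 "m": 0.09334858235688673,
 "Xf": 0.04272766986172839,
 "q": 0.8536540338495611,
 "r": 0.005247861351471362,
 "Nai": 9.714513040803432,
 "mL": 0.0018135653278182919,
 "hL": 0.10915000664422689,
 "RyRa": 0.04635325415294431,
 "RyRo": 0.00011122962480997608,
 "RyRc": 0.877154322182273,
 "Xr1": 0.12330937635364782,
 "Xr2": 0.4405720202070671,
 "Xs": 0.029280429607291675,
 "N": 0.9999544680551852,
 "XBprer": 7.313821926108246e-06,
 "XBpostr": 3.70920752260942e-05,
 "xXBprer": 9.456607970782453e-05,
 "xXBpostr": 0.00714910382689705,
 "TRPNCaL": 0.016379604636953645,
 "TRPNCaH": 0.14380925356098936,
 "N_NoXB": 0.9999990093849268,
 "SL": 1.881173438043614,
 "intf": -5.3881577312717815e-05
}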
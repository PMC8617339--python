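{
 "Vm": -0.07479447898074446,
 "CaSR": 0.09786829693693914,
 "Cai": 1.755582606149868e-05,
 "d": 8.393113358826645e-05,
 "f1": 0.9749466559746928,
 "f2": 0.9999853139558936,
 "fCa": 0.9989545796419588,
 "h": 0.7921161807079407,
 "j": 0.2211331006840445,
 "m": 0.10031265230679354,
 "Xf": 0.08464801044111843,
 "q": 0.8433664994744131,
 "r": 0.005598859564189004,
 "Nai": 9.162552976910582,
 "mL": 0.0023093146557504954,
 "hL": 0.1473217846570646,
 "RyRa": 0.035202145862215616,
 "RyRo": 0.00011232722961503572,
 "RyRc": 0.9936864451254996,
 "Xr1": 0.012567118785694062,
 "Xr2": 0.4343962389918443,
 "Xs": 0.031459280351972756,
 "N": 0.9999991245374503,
 "XBprer": 1.4087276818104114e-07,
 "XBpostr": 6.698076287779769e-07,
 "xXBprer": 1.0594099342767528e-05,
 "xXBpostr": 0.007016701670862202,
 "TRPNCaL": 0.010909743599337473,
 "TRPNCaH": 0.08624547367542988,
 "N_NoXB": 0.9999999368103819,
 "SL": 1.8979030414479172,
 "intf": -5.999843417907676e-06
}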
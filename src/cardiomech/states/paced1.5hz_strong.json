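{
 "Vm": -0.0755015983881877,
 "CaSR": 0.09463409459533813,
 "Cai": 2.8735972209026096e-05,
 "d": 7.595851165954722e-05,
 "f1": 0.8969587822610154,
 "f2": 0.9999866335426504,
 "fCa": 0.9982934353637183,
 "h": 0.7825366988412986,
 "j": 0.1169967346450821,
 "m": 0.09638858278005905,
 "Xf": 0.04370745687555869,
 "q": 0.8480836389072043,
 "r": 0.0054085433037431825,
 "Nai": 9.974231656152337,
 "mL": 0.0020196765363884733,
 "hL": 0.10606995576464823,
 "RyRa": 0.047311085210390194,
 "RyRo": 0.00018491050643830591,
 "RyRc": 0.8737021608444356,
 "Xr1": 0.11476011015144397,
 "Xr2": 0.43777270989888,
 "Xs": 0.030312568789555887,
 "N": 0.9999587637198701,
 "XBprer": 6.627172853460096e-06,
 "XBpostr": 3.309526752169774e-05,
 "xXBprer": 7.613462912148966e-05,
 "xXBpostr": 0.007120028741261316,
 "TRPNCaL": 0.018084802007360998,
 "TRPNCaH": 0.15184758255329842,
 "N_NoXB": 0.9999985972450094,
 "SL": 1.8843841619505883,
 "intf": -4.475425210160079e-05
}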
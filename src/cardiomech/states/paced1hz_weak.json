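{
 "Vm": -0.0747698809214222,
 "CaSR": 0.11542502326250707,
 "Cai": 1.6018009015432035e-05,
 "d": 8.421539095257643e-05,
 "f1": 0.9692774815364923,
 "f2": 0.9999853439328272,
 "fCa": 0.9990445718033056,
 "h": 0.7937669686031184,
 "j": 0.2209814291954428,
 "m": 0.10045191510079009,
 "Xf": 0.08454123985800864,
 "q": 0.843372157657565,
 "r": 0.005604383865915341,
 "Nai": 8.867304187580478,
 "mL": 0.002320098262381925,
 "hL": 0.14981097784896302,
 "RyRa": 0.03397358344647804,
 "RyRo": 9.908809937856686e-05,
 "RyRc": 0.9935550297157365,
 "Xr1": 0.013624753544168802,
 "Xr2": 0.4342866597581773,
 "Xs": 0.031486091654520286,
 "N": 0.9999992881946879,
 "XBprer": 1.144698085782579e-07,
 "XBpostr": 5.573621719775627e-07,
 "xXBprer": 1.3106813501240014e-05,
 "xXBpostr": 0.007020663260484821,
 "TRPNCaL": 0.009949042585788265,
 "TRPNCaH": 0.07902087934153074,
 "N_NoXB": 0.9999999616126328,
 "SL": 1.8974285671044246,
 "intf": -7.354289876560699e-06
}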
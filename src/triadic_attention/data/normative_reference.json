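{
  "sd_multiplier": 2.0,
  "domains": {
    "AvgCon": {"na_mean": 6.09, "na_sd": 0.94, "flag_high": true, "flag_low": true, "asc_mean": 7.73},
    "AvgNoCon": {"na_mean": 30.95, "na_sd": 15.11, "flag_high": true, "flag_low": false, "asc_mean": 58.6},
    "NumCon": {"na_mean": 2.14, "na_sd": 0.47, "flag_high": false, "flag_low": true, "asc_mean": 1.44},
    "MaxExc": {"na_mean": 9.38, "na_sd": 5.89, "flag_high": true, "flag_low": false, "asc_mean": 20.3},
    "ExcPct": {"na_mean": 3.13, "na_sd": 1.85, "flag_high": true, "flag_low": false, "asc_mean": 7.4}
  }
}
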
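{
  "pi_fst_windows.tsv": "71c168936e98be638a0c671bc4341041e435b1ca9196092054bcf1ff49719282",
  "pi_fst_selected.bed": "9b1d77adc5ca67289aa3f890dfa4ee0fb820eea01cf945c642c69883aa7639c0",
  "xpclr_windows.tsv": "ec1e685f4e6d177178d10cbdcd9b76d8add9f3bbee1368723fbe7276445bf002",
  "xpclr_selected.bed": "90a00ca585e4779c73456ba7c4a62e6d861d686ad8ab1a03febf4bd97cd1d0e3",
  "regions_pifst.bed": "dda9cc5cc0ea06f2706084788ae8dc04c9810772ea2498e2ab75cbf19cefd106",
  "regions_xpclr.bed": "a7efc5979f3b800957de6d7e82edbb3fc1ed16e33ae8c8bef0169b2cbcc722f7",
  "regions_intersection.bed": "0e31928ca0f1bbdce4ef1748b41fed84e0373357a61df449f196bc0dfb0238ec",
  "genes_pifst.tsv": "0e06116288470bac8a28ebd6e673edf72a11725c069e0cd4533ec2cceff26f13",
  "genes_xpclr.tsv": "d8eba06494798f6ce2a4127ae4ab8925bce4d0ae5f2563212d1b23fd6c0deddb",
  "genes_union.tsv": "0e06116288470bac8a28ebd6e673edf72a11725c069e0cd4533ec2cceff26f13",
  "genes_intersection.tsv": "d8eba06494798f6ce2a4127ae4ab8925bce4d0ae5f2563212d1b23fd6c0deddb",
  "daf.tsv": "715cc7bc76dee341b8ccbb8ba52e2c21d76d6f9dac596805d382188b87c84da6",
  "daf_high.tsv": "44351c79e8cd826f3a02b6486c73a252a0fec2ee5cd3616c8ea1167d68cd88f9",
  "summary.tsv": "9c43ab6ea24744e001a46228774d2e55b5ca6d4002b43fcc8b7afe4d1e2d5662"
}
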
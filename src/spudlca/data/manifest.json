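{
 "files": {
  "table1_raw.csv": {
   "sha256": "428bb4122f8bf9bc56c3c940734bb70fe3a6892f82bd64b056799d5be3c12f68",
   "provenance": "printed",
   "description": "mineral composition of raw potatoes by storage condition/time"
  },
  "table2_baked.csv": {
   "sha256": "1e680d8ea8b314e3b080ce897c21572868fb8a360714a620659e21df771aad7e",
   "provenance": "printed",
   "description": "mineral composition of baked potatoes"
  },
  "table3_fried.csv": {
   "sha256": "165e522f2292b5885b2910a04b729d02ed8275a44bc93be3e32c65b0063bc98e",
   "provenance": "printed",
   "description": "mineral composition of fried potatoes"
  },
  "tableS_boiled_synthetic.csv": {
   "sha256": "62ef182a828b7be57f3e1744600106eeb5b5f65b66d3bf093f6f928763818d36",
   "provenance": "synthetic",
   "description": "generator stand-in for the unpublished boiled-pathway supplement"
  },
  "table4_uncertainty.csv": {
   "sha256": "82e7eaa21837498073ed8a2536c6f2bbb7de9bb73001d0d3a4fbecf47115061c",
   "provenance": "printed",
   "description": "Monte Carlo mean/SD/CV and 5th/95th bounds for the two highest-impact scenarios"
  },
  "printed_midpoints.csv": {
   "sha256": "1b63b92a0b8558688c9bf8579d68d6e1787949e2b42c42a8bd6a0392b2fefb1c",
   "provenance": "printed",
   "description": "midpoint impact values quoted in the study text"
  },
  "printed_endpoints.csv": {
   "sha256": "c64b26be5c53ed700f6a9b4bf1dd667584a818fd1f967f496ef27d2011aaea7d",
   "provenance": "printed",
   "description": "endpoint damage values quoted in the study text"
  },
  "printed_topsis.csv": {
   "sha256": "7f4068354d9788159c36d7cb1009672e5b1985537c1e189bb1cfc6118a21dbbb",
   "provenance": "printed",
   "description": "top-3 TOPSIS closeness scores per priority context"
  }
 }
}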
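{
  "description": "Entrez IDs of differentially expressed genes reported for the two GEO cohorts (PD column is the top 50 by p-value). Packaged for reference; no overlap claims are derived from them.",
  "AD": [55076, 66005, 114801, 6474, 51084, 114041, 2694, 1184, 10859, 347735,
         53836, 3339, 254295, 51147, 147808, 26050, 152573, 51412, 100289341, 27309,
         285194, 51678, 374920, 135228, 5788, 5819, 1051, 4985, 50717, 1293, 100128927,
         4199, 6921, 2036, 1769, 148066, 57633, 10369],
  "PD": [4719, 7443, 22877, 5725, 5451, 10644, 138151, 100272216, 60496, 7414,
         2872, 54839, 23313, 4345, 8140, 404672, 55750, 10097, 81853, 5521,
         9201, 55209, 8905, 4190, 902, 8382, 56675, 5955, 5567, 7260,
         5862, 11179, 30827, 400, 23242, 37, 51382, 9554, 54541, 9804,
         801, 29887, 4839, 7994, 64175, 23158, 1114, 1353, 65055, 23462]
}
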
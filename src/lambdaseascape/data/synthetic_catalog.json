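{
 "loci": [
  {
   "index": 0,
   "position": 3034,
   "wt": "A",
   "mut": "G",
   "watermarks": [
    {
     "position": 3036,
     "wt": "G",
     "mut": "A"
    },
    {
     "position": 3039,
     "wt": "G",
     "mut": "A"
    }
   ],
   "ompf_required": true
  },
  {
   "index": 1,
   "position": 3052,
   "wt": "G",
   "mut": "A",
   "watermarks": [
    {
     "position": 3054,
     "wt": "A",
     "mut": "G"
    },
    {
     "position": 3057,
     "wt": "T",
     "mut": "C"
    }
   ],
   "ompf_required": false
  },
  {
   "index": 2,
   "position": 3076,
   "wt": "A",
   "mut": "G",
   "watermarks": [
    {
     "position": 3078,
     "wt": "C",
     "mut": "T"
    },
    {
     "position": 3081,
     "wt": "T",
     "mut": "C"
    }
   ],
   "ompf_required": false
  },
  {
   "index": 3,
   "position": 3103,
   "wt": "A",
   "mut": "G",
   "watermarks": [
    {
     "position": 3105,
     "wt": "A",
     "mut": "G"
    },
    {
     "position": 3108,
     "wt": "A",
     "mut": "G"
    }
   ],
   "ompf_required": false
  },
  {
   "index": 4,
   "position": 3127,
   "wt": "C",
   "mut": "T",
   "watermarks": [
    {
     "position": 3129,
     "wt": "C",
     "mut": "T"
    },
    {
     "position": 3132,
     "wt": "T",
     "mut": "C"
    }
   ],
   "ompf_required": false
  },
  {
   "index": 5,
   "position": 3151,
   "wt": "G",
   "mut": "A",
   "watermarks": [
    {
     "position": 3153,
     "wt": "T",
     "mut": "C"
    },
    {
     "position": 3156,
     "wt": "G",
     "mut": "A"
    }
   ],
   "ompf_required": false
  },
  {
   "index": 6,
   "position": 3175,
   "wt": "G",
   "mut": "A",
   "watermarks": [
    {
     "position": 3177,
     "wt": "T",
     "mut": "C"
    },
    {
     "position": 3180,
     "wt": "C",
     "mut": "T"
    }
   ],
   "ompf_required": false
  },
  {
   "index": 7,
   "position": 3199,
   "wt": "T",
   "mut": "C",
   "watermarks": [
    {
     "position": 3201,
     "wt": "T",
     "mut": "C"
    },
    {
     "position": 3204,
     "wt": "T",
     "mut": "C"
    }
   ],
   "ompf_required": false
  },
  {
   "index": 8,
   "position": 3319,
   "wt": "G",
   "mut": "A",
   "watermarks": [
    {
     "position": 3312,
     "wt": "T",
     "mut": "C"
    },
    {
     "position": 3315,
     "wt": "T",
     "mut": "C"
    }
   ],
   "ompf_required": true
  },
  {
   "index": 9,
   "position": 3321,
   "wt": "T",
   "mut": "A",
   "watermarks": [
    {
     "position": 3324,
     "wt": "A",
     "mut": "G"
    },
    {
     "position": 3327,
     "wt": "A",
     "mut": "G"
    }
   ],
   "ompf_required": true
  }
 ],
 "amplicon": {
  "offset": 3000,
  "sequence": "ACAACGGCACTCCACTCTCTTGTGCCGCTTTCAATGTTGCCCTGGGTAGAAGCACGTGTCTAAGTAATCGAAAACATCGTTGGCTAAAGTACCCGGTCTTTTATAGCATAAACGCGAAGGAAGGCCCACTGTCGGCTTGATGGGGGATCGGCTTTGTTGTCTTCCCTCACTACCGCTATCATGATTGCCCGGGTGCAGTTTGTTAATCGTACGTGCTAGTGACGGTAAGTTCGAACTAGAAGAGCTCCTTTTCCATTATGTCATTGTCTTTGCCCCCGGAGTTCCATCGGCTGTTTTGGGAAGCCGTAGATTTTTCACGATAGATAAATTAAGTTCCCGAAAAATCTTAGAGACATACTGGCCCGTTGAGCAAAAGTCTATATTATTATGGGGGGTAGCA"
 }
}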
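{
 "version": 1,
 "bases": {
  "A": {
   "atoms": {
    "C1'": [
     0.0,
     0.0
    ],
    "C2": [
     2.967782,
     3.192799
    ],
    "C4": [
     2.275941,
     1.104826
    ],
    "C5": [
     3.569976,
     0.616831
    ],
    "C6": [
     4.609267,
     1.563756
    ],
    "C8": [
     2.297068,
     -1.085103
    ],
    "N1": [
     4.267463,
     2.870767
    ],
    "N3": [
     1.901814,
     2.395739
    ],
    "N6": [
     5.904874,
     1.241842
    ],
    "N7": [
     3.569893,
     -0.771096
    ],
    "N9": [
     1.459,
     -0.0
    ]
   },
   "ring_atoms": [
    "N9",
    "C8",
    "N7",
    "C5",
    "C6",
    "N1",
    "C2",
    "N3",
    "C4"
   ],
   "glyco_atom": "N9",
   "frame_atoms": [
    "N9",
    "C4",
    "C8"
   ],
   "chi_partner": "C4",
   "pseudo_chi_base_atoms": [
    "N9",
    "N1"
   ],
   "c4c5_bond": [
    "C4",
    "C5"
   ]
  },
  "G": {
   "atoms": {
    "C1'": [
     0.0,
     0.0
    ],
    "C2": [
     2.893639,
     3.232775
    ],
    "C4": [
     2.277003,
     1.105146
    ],
    "C5": [
     3.563047,
     0.607534
    ],
    "C6": [
     4.64992,
     1.519826
    ],
    "C8": [
     2.287965,
     -1.095771
    ],
    "N1": [
     4.208994,
     2.8391
    ],
    "N2": [
     2.674033,
     4.555671
    ],
    "N3": [
     1.871502,
     2.3928
    ],
    "N7": [
     3.55436,
     -0.780468
    ],
    "N9": [
     1.459,
     -0.0
    ],
    "O6": [
     5.862493,
     1.275216
    ]
   },
   "ring_atoms": [
    "N9",
    "C8",
    "N7",
    "C5",
    "C6",
    "N1",
    "C2",
    "N3",
    "C4"
   ],
   "glyco_atom": "N9",
   "frame_atoms": [
    "N9",
    "C4",
    "C8"
   ],
   "chi_partner": "C4",
   "pseudo_chi_base_atoms": [
    "N9",
    "N1"
   ],
   "c4c5_bond": [
    "C4",
    "C5"
   ]
  },
  "C": {
   "atoms": {
    "C1'": [
     0.0,
     -0.0
    ],
    "C2": [
     2.133834,
     1.230986
    ],
    "C4": [
     4.173097,
     0.105394
    ],
    "C5": [
     3.522703,
     -1.162355
    ],
    "C6": [
     2.183795,
     -1.16775
    ],
    "N1": [
     1.473,
     -0.0
    ],
    "N3": [
     3.486778,
     1.250389
    ],
    "N4": [
     5.50634,
     0.173862
    ],
    "O2": [
     1.459451,
     2.271566
    ]
   },
   "ring_atoms": [
    "N1",
    "C2",
    "N3",
    "C4",
    "C5",
    "C6"
   ],
   "glyco_atom": "N1",
   "frame_atoms": [
    "N1",
    "C2",
    "C6"
   ],
   "chi_partner": "C2",
   "pseudo_chi_base_atoms": [
    "N1",
    "N3"
   ],
   "c4c5_bond": [
    "C4",
    "C5"
   ]
  },
  "U": {
   "atoms": {
    "C1'": [
     0.0,
     -0.0
    ],
    "C2": [
     2.114668,
     1.222909
    ],
    "C4": [
     4.263273,
     0.016602
    ],
    "C5": [
     3.523625,
     -1.208386
    ],
    "C6": [
     2.187061,
     -1.175058
    ],
    "N1": [
     1.473,
     0.0
    ],
    "N3": [
     3.486103,
     1.156949
    ],
    "O2": [
     1.513846,
     2.283557
    ],
    "O4": [
     5.490814,
     0.121317
    ]
   },
   "ring_atoms": [
    "N1",
    "C2",
    "N3",
    "C4",
    "C5",
    "C6"
   ],
   "glyco_atom": "N1",
   "frame_atoms": [
    "N1",
    "C2",
    "C6"
   ],
   "chi_partner": "C2",
   "pseudo_chi_base_atoms": [
    "N1",
    "N3"
   ],
   "c4c5_bond": [
    "C4",
    "C5"
   ]
  }
 }
}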
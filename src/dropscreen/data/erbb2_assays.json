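{
  "comment": "ERBB2 screening assay + six WT-MUT duplex definitions. Amplitudes are the synthetic generator's default cluster rendering (arbitrary fluorescence units). The 17-variant membership is reconstructed from the published assay description (Table S3 is not distributed): the 12 named targets plus the two exon-20 duplications plus three additional 776-779 hotspot substitutions (G776S, G776delinsVC, S779F) flagged 'reconstructed'.",
  "screening": {
    "name": "ERBB2-S",
    "amplicons": [
      {
        "id": "a310",
        "codon_range": [305, 315],
        "probes": [
          {"name": "S310F-probe", "channel": "FAM", "role": "mutation-specific", "amplitude": 3000, "targets": ["S310F"]},
          {"name": "S310Y-probe", "channel": "FAM", "role": "mutation-specific", "amplitude": 3000, "targets": ["S310Y"]}
        ]
      },
      {
        "id": "a755_769",
        "codon_range": [750, 770],
        "probes": [
          {"name": "L755S-probe", "channel": "HEX", "role": "mutation-specific", "amplitude": 9000, "targets": ["L755S"]},
          {"name": "D769H-probe", "channel": "HEX", "role": "mutation-specific", "amplitude": 9000, "targets": ["D769H"]},
          {"name": "D769Y-probe", "channel": "HEX", "role": "mutation-specific", "amplitude": 9000, "targets": ["D769Y"]}
        ]
      },
      {
        "id": "a772_780",
        "codon_range": [772, 780],
        "probes": [
          {"name": "DO-776-779", "channel": "FAM", "role": "drop-off", "amplitude": 6000,
           "targets": ["WT", "Y772_A775dup", "G778_P780dup"]},
          {"name": "REF-772-780", "channel": "Cy5", "role": "reference", "amplitude": 6000,
           "targets": ["WT", "Y772_A775dup", "G778_P780dup",
                       "G776V", "G776S", "G776delinsVC",
                       "V777L(G>C)", "V777L(G>T)", "V777M", "S779F",
                       "G778_S779insLPG", "G778_S779insLPS"]},
          {"name": "Y772_A775dup-probe", "channel": "HEX", "role": "mutation-specific", "amplitude": 2000, "targets": ["Y772_A775dup"]},
          {"name": "G778_P780dup-probe", "channel": "HEX", "role": "mutation-specific", "amplitude": 3200, "targets": ["G778_P780dup"]}
        ]
      },
      {
        "id": "a869",
        "codon_range": [865, 872],
        "probes": [
          {"name": "L869R-probe", "channel": "HEX", "role": "mutation-specific", "amplitude": 9000, "targets": ["L869R"]}
        ]
      }
    ],
    "groups": [
      {"name": "WT", "plane": ["FAM", "Cy5"], "members": ["WT"]},
      {"name": "S310F/Y", "plane": ["FAM", "Cy5"], "members": ["S310F", "S310Y"]},
      {"name": "L755S-D769H/Y-L869R", "plane": ["FAM", "HEX"], "members": ["L755S", "D769H", "D769Y", "L869R"]},
      {"name": "Y772_A775dup-G778_P780dup", "plane": ["FAM", "HEX"], "members": ["Y772_A775dup", "G778_P780dup"]},
      {"name": "776-779_MUT", "plane": ["FAM", "Cy5"],
       "members": ["G776V", "G776S", "G776delinsVC", "V777L(G>C)", "V777L(G>T)", "V777M", "S779F",
                   "G778_S779insLPG", "G778_S779insLPS"]}
    ],
    "reconstructed_members": ["G776S", "G776delinsVC", "S779F"]
  },
  "variants": {
    "S310F":  {"cdna": "c.929C>T",       "aliases": []},
    "S310Y":  {"cdna": "c.929C>A",       "aliases": []},
    "L755S":  {"cdna": "c.2264T>C",      "aliases": []},
    "D769H":  {"cdna": "c.2305G>C",      "aliases": []},
    "D769Y":  {"cdna": "c.2305G>T",      "aliases": []},
    "L869R":  {"cdna": "c.2606T>G",      "aliases": []},
    "Y772_A775dup": {"cdna": "c.2313_2324dup",
                     "aliases": ["A775-G776insYVMA", "A775_G776insYVMA", "M774_A775insAYVM", "c.2313_2324dup"]},
    "G778_P780dup": {"cdna": "c.2331_2339dup",
                     "aliases": ["P780_Y781insGSP", "P780-Y781insGSP", "c.2331_2339dup", "c.2332_2340dup"]},
    "G776V":  {"cdna": "c.2327G>T",      "aliases": []},
    "G776S":  {"cdna": "c.2326G>A",      "aliases": [], "reconstructed": true},
    "G776delinsVC": {"cdna": "c.2326_2328delinsGTTTGT", "aliases": ["G776>VC"], "reconstructed": true},
    "V777L(G>C)": {"cdna": "c.2329G>C",  "aliases": ["V777L c.2329G>C"]},
    "V777L(G>T)": {"cdna": "c.2329G>T",  "aliases": ["V777L c.2329G>T"]},
    "V777M":  {"cdna": "c.2329G>A",      "aliases": []},
    "S779F":  {"cdna": "c.2336C>T",      "aliases": [], "reconstructed": true},
    "G778_S779insLPG": {"cdna": "c.2334_2335insCTGCCTG", "aliases": []},
    "G778_S779insLPS": {"cdna": "c.2334_2335insCTTCCAG", "aliases": []}
  },
  "duplexes": [
    {
      "name": "duplex-S310F/Y",
      "screen_group": "S310F/Y",
      "amplicon": {"id": "a310", "codon_range": [305, 315], "probes": [
        {"name": "WT-310-probe", "channel": "HEX", "role": "wild-type", "amplitude": 7000, "targets": ["WT"]},
        {"name": "S310F-mut", "channel": "FAM", "role": "mutation-specific", "amplitude": 4000, "targets": ["S310F"]},
        {"name": "S310Y-mut", "channel": "FAM", "role": "mutation-specific", "amplitude": 8000, "targets": ["S310Y"]}
      ]}
    },
    {
      "name": "duplex-L755S",
      "screen_group": "L755S-D769H/Y-L869R",
      "amplicon": {"id": "a755", "codon_range": [750, 760], "probes": [
        {"name": "WT-755-probe", "channel": "HEX", "role": "wild-type", "amplitude": 7000, "targets": ["WT"]},
        {"name": "L755S-mut", "channel": "FAM", "role": "mutation-specific", "amplitude": 6000, "targets": ["L755S"]}
      ]}
    },
    {
      "name": "duplex-D769H/Y",
      "screen_group": "L755S-D769H/Y-L869R",
      "amplicon": {"id": "a769", "codon_range": [765, 772], "probes": [
        {"name": "WT-769-probe", "channel": "HEX", "role": "wild-type", "amplitude": 7000, "targets": ["WT"]},
        {"name": "D769H-mut", "channel": "FAM", "role": "mutation-specific", "amplitude": 4000, "targets": ["D769H"]},
        {"name": "D769Y-mut", "channel": "FAM", "role": "mutation-specific", "amplitude": 8000, "targets": ["D769Y"]}
      ]}
    },
    {
      "name": "duplex-L869R",
      "screen_group": "L755S-D769H/Y-L869R",
      "amplicon": {"id": "a869", "codon_range": [865, 872], "probes": [
        {"name": "WT-869-probe", "channel": "HEX", "role": "wild-type", "amplitude": 7000, "targets": ["WT"]},
        {"name": "L869R-mut", "channel": "FAM", "role": "mutation-specific", "amplitude": 6000, "targets": ["L869R"]}
      ]}
    },
    {
      "name": "duplex-776-779",
      "screen_group": "776-779_MUT",
      "amplicon": {"id": "a772_780", "codon_range": [772, 780], "probes": [
        {"name": "WT-776-probe", "channel": "HEX", "role": "wild-type", "amplitude": 7000, "targets": ["WT"]},
        {"name": "G776V-mut", "channel": "FAM", "role": "mutation-specific", "amplitude": 2000, "targets": ["G776V"]},
        {"name": "V777L-GC-mut", "channel": "FAM", "role": "mutation-specific", "amplitude": 4000, "targets": ["V777L(G>C)"]},
        {"name": "V777L-GT-mut", "channel": "FAM", "role": "mutation-specific", "amplitude": 6000, "targets": ["V777L(G>T)"]},
        {"name": "V777M-mut", "channel": "FAM", "role": "mutation-specific", "amplitude": 8000, "targets": ["V777M"]},
        {"name": "insLPG-mut", "channel": "FAM", "role": "mutation-specific", "amplitude": 10000, "targets": ["G778_S779insLPG"]},
        {"name": "insLPS-mut", "channel": "FAM", "role": "mutation-specific", "amplitude": 12000, "targets": ["G778_S779insLPS"]}
      ]}
    },
    {
      "name": "duplex-dup",
      "screen_group": "Y772_A775dup-G778_P780dup",
      "amplicon": {"id": "a772_780", "codon_range": [772, 780], "probes": [
        {"name": "WT-772-780-probe", "channel": "HEX", "role": "wild-type", "amplitude": 7000, "targets": ["WT"]},
        {"name": "Y772_A775dup-mut", "channel": "FAM", "role": "mutation-specific", "amplitude": 4000, "targets": ["Y772_A775dup"]},
        {"name": "G778_P780dup-mut", "channel": "FAM", "role": "mutation-specific", "amplitude": 8000, "targets": ["G778_P780dup"]}
      ]}
    }
  ]
}
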
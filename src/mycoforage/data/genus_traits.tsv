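genus	exploration_type	hydrophobicity	expectation
Amanita	medium-distance smooth	hydrophobic	uncertain
Amphinema	medium-distance fringe	hydrophobic	prolific in soil bags
Cenococcum	short-distance	hydrophilic	prolific in all bags
Cortinarius	medium-distance fringe	hydrophobic	prolific in soil bags
Hyaloscypha	contact	hydrophilic	little colonisation of bags
Hygrophorus	short-distance	unknown	prolific in all bags
Lactarius	contact	hydrophilic	little colonisation of bags
Piloderma	medium-distance fringe	hydrophobic	prolific in soil bags
Pseudotomentella	medium-distance smooth	hydrophilic	prolific in all bags
Russula	contact	hydrophilic	little colonisation of bags
Tomentella	medium-distance smooth	hydrophilic	prolific in all bags
Tylospora	short-distance	hydrophilic	prolific in all bags
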
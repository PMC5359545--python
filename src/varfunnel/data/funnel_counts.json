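{
  "stages": ["trio", "species_specific", "phenotype_segregation", "gene_list"],
  "counts": {
    "trio": {
      "stop_gain": 678,
      "start_stop_loss": 134,
      "splice_donor_acceptor": 2547,
      "exon_deletion": 4,
      "frameshift": 3602,
      "rare_amino_acid": 0,
      "codon_alteration": 1462,
      "missense": 47534,
      "splice_branch": 0,
      "utr_deletion": 0,
      "low_other": 89718,
      "modifier": 22064948
    },
    "species_specific": {
      "stop_gain": 454,
      "start_stop_loss": 330,
      "splice_donor_acceptor": 88,
      "exon_deletion": 1,
      "frameshift": 722,
      "rare_amino_acid": 0,
      "codon_alteration": 711,
      "missense": 32038,
      "splice_branch": 0,
      "utr_deletion": 0,
      "low_other": 59119,
      "modifier": 13437721
    },
    "phenotype_segregation": {
      "stop_gain": 8,
      "start_stop_loss": 0,
      "splice_donor_acceptor": 22,
      "exon_deletion": 0,
      "frameshift": 20,
      "rare_amino_acid": 0,
      "codon_alteration": 13,
      "missense": 595,
      "splice_branch": 0,
      "utr_deletion": 0,
      "low_other": 859,
      "modifier": 232512
    },
    "gene_list": {
      "stop_gain": 0,
      "start_stop_loss": 0,
      "splice_donor_acceptor": 0,
      "exon_deletion": 0,
      "frameshift": 1,
      "rare_amino_acid": 0,
      "codon_alteration": 0,
      "missense": 7,
      "splice_branch": 0,
      "utr_deletion": 0,
      "low_other": 13,
      "modifier": 1019
    }
  }
}
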
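"""Shared alphabets and symbols."""

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"  # 20 canonical residues, fixed order
PAD_SYMBOL = "-"
CDR3_ALPHABET = AMINO_ACIDS + PAD_SYMBOL  # 21 symbols; padding is last
AA_INDEX = {aa: i for i, aa in enumerate(CDR3_ALPHABET)}
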
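"""Amino-acid alphabet constants used by every encoder.

Two fixed residue orderings matter throughout the package:

* ``AA_ALPHABET`` — the 20 standard amino acids in alphabetical one-letter
  order.  Amino-acid composition (AC), dipeptide composition (DC) and the
  PSSM composition are all indexed in this order.
* ``MM_ORDER`` — the same 20 residues sorted from most to least abundant in
  the average bacterial hemoglobin-like (HbL) protein.  The MM profile is
  the AC vector re-indexed by this ordering.
"""

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
"""The 20 standard amino acids, alphabetical one-letter codes."""

MM_ORDER = "ALEKIVGDPNFQRTMYSHWC"
"""Residues ordered from most to least abundant in average HbL sequences."""

AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

#: Dipeptide labels in row-major order: first residue alphabetical (outer),
#: second residue alphabetical (inner).  DC vectors use this indexing.
DIPEPTIDES = tuple(a + b for a in AA_ALPHABET for b in AA_ALPHABET)

#: Classic PSI-BLAST column ordering used in ASCII PSSM files.
PSIBLAST_COLUMN_ORDER = "ARNDCQEGHILKMFPSTWYV"

assert sorted(MM_ORDER) == sorted(AA_ALPHABET)
assert sorted(PSIBLAST_COLUMN_ORDER) == sorted(AA_ALPHABET)
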
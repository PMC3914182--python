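"""Bundled reference constants for the rainbow trout miR-122 study system.

These few sequences and gene names are the published anchors of the analysis:
the working mature omy-miR-122 sequence (the validated qPCR forward primer
for the mature form, expressed as RNA; a proxy for the exact mature species),
the 13-nt seed-anchored LNA antagomir used to silence all miR-122 isomiRs in
vivo, the non-targeted miRNAs used as specificity controls, and the miR-122
targets conserved between rainbow trout and mouse.
"""

from __future__ import annotations

from .sequences import Alphabet, NucSequence
from .target_prediction import MatureMirna

# Mature omy-miR-122 working sequence (DNA primer form and its RNA coercion).
MIR122_MATURE_PRIMER_DNA = "TGGAGTGTGACAATGGTGTTTGT"
MIR122_MATURE_RNA = MIR122_MATURE_PRIMER_DNA.replace("T", "U")

# 13-nt LNA inhibitor, the reverse complement of mature positions 2-14,
# anchored at the seed (positions 2-7) so every 3' isomiR is covered.
LNA_122I = "ATTGTCACACTCC"

# miR-122 targets conserved between the trout prediction and the mouse
# knock-out target catalogue (9 genes of 83 predicted trout targets -> 11%).
CONSERVED_TARGET_GENES = (
    "dditl4",
    "igf2",
    "parp3",
    "rtn3",
    "serpinh1",
    "socs6",
    "ucp2a",
    "slc2a1",
    "adam10",
)
N_PREDICTED_TROUT_TARGETS = 83
N_MAPPED_HOMOLOGS = 76
N_TROUT_UTRS = 1059


def mir122_mature() -> MatureMirna:
    """The mature omy-miR-122 working sequence as an RNA MatureMirna."""
    return MatureMirna(
        "omy-miR-122",
        NucSequence("omy-miR-122", MIR122_MATURE_RNA, Alphabet.RNA),
    )
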
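"""Shared amino-acid alphabets and canonical background composition.

Every stochastic component of the package (sequence simulation, profile
pseudocounts, null models for score calibration) draws on one canonical
background distribution so that scores are comparable across modules.
"""

from __future__ import annotations

import numpy as np

#: Canonical amino-acid ordering used for all vectorised emission tables.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Background amino-acid frequencies (Robinson & Robinson style composition,
#: the composition conventionally used for protein database statistics).
BACKGROUND_FREQS = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}

#: Background frequencies as a vector in AMINO_ACIDS order, renormalised.
BACKGROUND = np.array([BACKGROUND_FREQS[a] for a in AMINO_ACIDS], dtype=float)
BACKGROUND /= BACKGROUND.sum()

#: Composition for simulated soluble (non-membrane) protein segments:
#: the background with strongly hydrophobic residues depleted, mimicking the
#: residue usage of extracellular/cytoplasmic soluble domains.  Using it for
#: loops and sensor domains keeps simulated membrane helices the only
#: hydropathy peaks, as in real receptors.
_HYDROPHOBIC_DEPLETION = {"A": 0.6, "C": 0.5, "F": 0.35, "I": 0.35, "L": 0.35,
                          "M": 0.5, "V": 0.35, "W": 0.5}
SOLUBLE_BACKGROUND = np.array(
    [BACKGROUND_FREQS[a] * _HYDROPHOBIC_DEPLETION.get(a, 1.0) for a in AMINO_ACIDS],
    dtype=float,
)
SOLUBLE_BACKGROUND /= SOLUBLE_BACKGROUND.sum()

#: Residue pool for simulated transmembrane helices.  Strongly hydrophobic
#: residues only, biased towards Leu/Ile/Val so that a 19-residue
#: Kyte-Doolittle window centred inside the helix scores well above the
#: detection threshold.
TM_RESIDUES = "AILVFMW"
TM_WEIGHTS = np.array([0.15, 0.20, 0.25, 0.20, 0.10, 0.07, 0.03], dtype=float)
TM_WEIGHTS /= TM_WEIGHTS.sum()

#: Karlin-Altschul constants for converting raw BLOSUM62 alignment scores to
#: bit scores: standard ungapped-approximation values, recorded here as the
#: single source of truth for the similarity-network statistics.
KA_LAMBDA = 0.3176
KA_K = 0.134


def aa_to_indices(seq: str) -> np.ndarray:
    """Encode a protein sequence as integer indices into AMINO_ACIDS.

    Unknown characters (X, B, Z, ...) raise ``ValueError`` — the simulator
    only emits the 20 canonical residues and the scanner requires them.
    """
    try:
        return np.array([AA_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"non-canonical residue {exc.args[0]!r} in sequence") from exc
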
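"""Primer melting temperature by nearest-neighbor thermodynamics.

Implements the unified nearest-neighbor parameter set of SantaLucia
(1998) with the associated entropy-based monovalent-salt correction.
Primer TMs in this package are always computed under a single fixed
ionic/primer-concentration regime so that designs are reproducible:

* monovalent cation concentration: 50 mM
* primer (excess strand) concentration: 250 nM
* TM model: Tm = 1000*dH / (dS + dS_salt + R*ln(C/4)) - 273.15

where dH is in kcal/mol, dS in cal/(mol*K), R = 1.987 cal/(mol*K) and
dS_salt = 0.368 * (N-1) * ln[Na+].
"""

from __future__ import annotations

import math

from .dna import revcomp

# Unified NN parameters (dH kcal/mol, dS cal/mol/K) for 5'->3' dinucleotide
# steps; the complementary step has identical values.
NN_PARAMS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
# terminal initiation penalties
INIT_GC = (0.1, -2.8)
INIT_AT = (2.3, 4.1)
# duplex symmetry correction for self-complementary sequences
SYM_CORR = (0.0, -1.4)

R_GAS = 1.987  # cal/(mol*K)
MONOVALENT_M = 0.05  # 50 mM
PRIMER_CONC_M = 250e-9  # 250 nM

_COMPLEMENT_STEP = {k: revcomp(k) for k in list(NN_PARAMS)}


class InvalidSequenceError(ValueError):
    """Sequence contains masked or non-ACGT characters."""


def _step_params(step: str) -> tuple[float, float]:
    if step in NN_PARAMS:
        return NN_PARAMS[step]
    return NN_PARAMS[revcomp(step)]


def melting_temperature(seq: str) -> float:
    """Duplex melting temperature (deg C) of a primer and its complement.

    Raises InvalidSequenceError for sequences containing N or other
    non-ACGT characters, and ValueError for sequences shorter than 8 nt
    (below any sensible primer length, where the NN model is unreliable).
    """
    seq = seq.upper()
    if any(b not in "ACGT" for b in seq):
        raise InvalidSequenceError(f"non-ACGT base in primer: {seq!r}")
    if len(seq) < 8:
        raise ValueError("primer too short for NN melting temperature (<8 nt)")

    dh, ds = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        h, s = INIT_GC if end in "GC" else INIT_AT
        dh += h
        ds += s
    for i in range(len(seq) - 1):
        h, s = _step_params(seq[i : i + 2])
        dh += h
        ds += s
    if seq == revcomp(seq):
        dh += SYM_CORR[0]
        ds += SYM_CORR[1]
        conc = PRIMER_CONC_M
    else:
        conc = PRIMER_CONC_M / 4.0

    ds_salt = 0.368 * (len(seq) - 1) * math.log(MONOVALENT_M)
    return 1000.0 * dh / (ds + ds_salt + R_GAS * math.log(conc)) - 273.15
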
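"""Packaged example data: the six-gene HMEC transition sequence.

The binarized transcriptomic trajectory of six integrin-pathway genes
(ITGB4, ITGA6, ITGA3, YWHAQ, CD151, ITGB1) measured in a human mammary
epithelial cell line at six time points after EGF stimulation:

    000000 -> 000000 -> 010000 -> 010000 -> 111000 -> 111001

i.e. 0 -> 0 -> 16 -> 16 -> 56 -> 57 in decimal.  The accompanying
expression matrix here is a *synthetic* stand-in constructed so that
per-gene Otsu binarization reproduces exactly this published binary
sequence; the raw microarray values are not redistributed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .inference import TransitionSequence

__all__ = [
    "HMEC_GENES",
    "HMEC_TIME_LABELS",
    "hmec_sequence",
    "hmec_expression",
]

HMEC_GENES = ("ITGB4", "ITGA6", "ITGA3", "YWHAQ", "CD151", "ITGB1")
HMEC_TIME_LABELS = ("1hr", "4hr", "8hr", "13hr", "18hr", "24hr")

_HMEC_BITS = (
    (0, 0, 0, 0, 1, 1),  # ITGB4
    (0, 0, 1, 1, 1, 1),  # ITGA6
    (0, 0, 0, 0, 1, 1),  # ITGA3
    (0, 0, 0, 0, 0, 0),  # YWHAQ
    (0, 0, 0, 0, 0, 0),  # CD151
    (0, 0, 0, 0, 0, 1),  # ITGB1
)

# Synthetic log2-scale intensities: low values ~7, high ~11, small
# within-class jitter so Otsu splits exactly at the published pattern.
# YWHAQ and CD151 are observed OFF throughout and are stored constant
# (binarized to zero under the default constant-gene policy).
_HMEC_VALUES = np.array(
    [
        [7.1, 7.3, 7.0, 7.2, 11.2, 11.0],
        [7.4, 7.2, 11.1, 10.9, 11.3, 11.2],
        [6.9, 7.2, 7.1, 7.0, 10.8, 11.1],
        [7.5, 7.5, 7.5, 7.5, 7.5, 7.5],
        [8.0, 8.0, 8.0, 8.0, 8.0, 8.0],
        [7.2, 7.0, 7.3, 7.1, 7.2, 11.0],
    ]
)


def hmec_sequence() -> TransitionSequence:
    """The published binarized six-gene trajectory (decimal 0,0,16,16,56,57)."""
    return TransitionSequence.from_bits(zip(*_HMEC_BITS), n=6)


def hmec_expression() -> pd.DataFrame:
    """Synthetic expression matrix that binarizes to :func:`hmec_sequence`."""
    return pd.DataFrame(
        _HMEC_VALUES.copy(), index=list(HMEC_GENES), columns=list(HMEC_TIME_LABELS)
    )
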
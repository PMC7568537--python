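"""Published summary statistics from a 2bRAD survey of two troglobionts.

Four caves on the southern Cumberland Plateau (Tennessee, USA) were
sampled for the cave spider *Nesticus barri* and the cave beetle
*Ptomaphagus hatchi*.  These tables carry the published per-cave and
per-pair summary statistics — cave lengths, pairwise F_ST estimates, and
nucleotide diversity / effective-size estimates under both the
genotype-likelihood ("gl") and hard-call ("hard") tracks.  They serve as
worked-example inputs for the arithmetic stages of the pipeline
(migration-rate inversion, Ne scaling, diversity-vs-length regression);
the underlying sequence data are not distributed here.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["cave_info", "pairwise_fst_table", "diversity_table"]

#: (cave, length in metres) for the four surveyed caves
_CAVES = [
    ("ST", 370),   # Solomon's Temple
    ("GV", 490),   # Grapevine
    ("SB", 1219),  # Sewanee Blowhole
    ("BT", 3142),  # Buggytop
]

# pair, watershed, species, weighted F_ST (GL), unweighted F_ST (GL),
# Weir-Cockerham F_ST (hard calls), mean d_XY (hard calls)
_PAIRWISE = [
    ("SB-ST", "same", "N. barri", 0.33, 0.12, 0.20, 0.14),
    ("BT-GV", "same", "N. barri", 0.42, 0.13, 0.29, 0.25),
    ("BT-ST", "different", "N. barri", 0.42, 0.14, 0.33, 0.31),
    ("BT-SB", "different", "N. barri", 0.43, 0.14, 0.32, 0.30),
    ("GV-ST", "different", "N. barri", 0.49, 0.15, 0.45, 0.33),
    ("GV-SB", "different", "N. barri", 0.52, 0.18, 0.45, 0.32),
    ("SB-ST", "same", "P. hatchi", 0.34, 0.18, 0.25, 0.21),
    ("BT-GV", "same", "P. hatchi", 0.30, 0.17, 0.16, 0.22),
    ("BT-ST", "different", "P. hatchi", 0.34, 0.17, 0.27, 0.25),
    ("BT-SB", "different", "P. hatchi", 0.32, 0.17, 0.15, 0.24),
    ("GV-ST", "different", "P. hatchi", 0.36, 0.19, 0.31, 0.25),
    ("GV-SB", "different", "P. hatchi", 0.36, 0.20, 0.22, 0.24),
]

# species, cave, pi (GL track), published Ne (GL), pi (hard calls),
# published Ne (hard); Ne values are the published roundings of pi/(4 mu)
# at mu = 2.8e-9
_DIVERSITY = [
    ("N. barri", "ST", 1.2e-3, 1.0e5, 1.6e-4, 1.4e4),
    ("N. barri", "GV", 1.4e-3, 1.2e5, 2.0e-4, 1.8e4),
    ("N. barri", "SB", 1.8e-3, 1.6e5, 2.1e-4, 1.9e4),
    ("N. barri", "BT", 2.6e-3, 2.3e5, 3.3e-4, 2.9e4),
    ("P. hatchi", "ST", 1.5e-3, 1.4e5, 1.2e-4, 1.0e4),
    ("P. hatchi", "GV", 1.9e-3, 1.7e5, 2.7e-4, 2.4e4),
    ("P. hatchi", "SB", 2.2e-3, 2.0e5, 3.3e-4, 2.9e4),
    ("P. hatchi", "BT", 2.4e-3, 2.2e5, 3.5e-4, 3.1e4),
]


def cave_info() -> pd.DataFrame:
    """Cave abbreviations and surveyed passage lengths (metres)."""
    return pd.DataFrame(_CAVES, columns=["cave", "length_m"])


def pairwise_fst_table() -> pd.DataFrame:
    """Published pairwise differentiation between the four caves."""
    return pd.DataFrame(
        _PAIRWISE,
        columns=[
            "pair", "watershed", "species",
            "weighted_fst", "unweighted_fst", "wc_fst", "dxy",
        ],
    )


def diversity_table() -> pd.DataFrame:
    """Published per-cave nucleotide diversity and Ne for both tracks."""
    df = pd.DataFrame(
        _DIVERSITY,
        columns=["species", "cave", "pi_gl", "ne_gl", "pi_hard", "ne_hard"],
    )
    return df.merge(cave_info(), on="cave")
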
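"""Published evaluation tables for the CDR-screening segmentation benchmark.

Three small tables of published numbers, shipped as data so that the margin
and ablation arithmetic around them is reproducible offline:

* ``CROSS_DOMAIN_TABLE`` — cross-domain comparison of domain-adaptive
  segmentation methods trained on the REFUGE training split and tested on
  Drishti-GS and RIM-ONE-r3 (cup/disc DSC and CDR error δ; methods that do
  not report δ carry NaN).
* ``REFUGE_LEADERBOARD`` — the REFUGE-challenge test-set leaderboard with
  per-metric ranks and overall weighted-rank scores.
* ``ABLATION_TABLE`` — component ablation on the REFUGE test set: the bare
  encoder/ASPP baseline, plus autoencoder augmentation (CAE), plus the
  boundary/mask adversarial branch pair (BMAL), plus the source-vs-enhanced
  boundary discriminator (D_b+).

Helper functions recompute the headline margins from the cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "CROSS_DOMAIN_TABLE",
    "REFUGE_LEADERBOARD",
    "ABLATION_TABLE",
    "delta_margin",
    "disc_dsc_margin",
    "ablation_delta_reduction",
]

CROSS_DOMAIN_TABLE = pd.DataFrame(
    [
        # method,        drishti cup, disc, delta,  rim-one cup, disc, delta
        ("BEAL",        0.862, 0.961, np.nan, 0.810, 0.898, np.nan),
        ("DoFE",        0.835, 0.955, np.nan, 0.800, 0.893, np.nan),
        ("CADA",        0.840, 0.890, 0.111,  0.640, 0.766, 0.087),
        ("CFEA",        0.827, 0.887, 0.113,  0.635, 0.751, 0.095),
        ("AdaptSegNet", 0.826, 0.881, 0.118,  0.627, 0.737, 0.102),
        ("DAE",         0.831, 0.940, np.nan, 0.790, 0.891, np.nan),
        ("SRDA",        0.807, 0.962, np.nan, 0.776, 0.894, np.nan),
        ("ours",        0.857, 0.962, 0.083,  0.791, 0.898, 0.082),
    ],
    columns=[
        "method",
        "drishti_dsc_cup", "drishti_dsc_disc", "drishti_delta",
        "rimone_dsc_cup", "rimone_dsc_disc", "rimone_delta",
    ],
)

REFUGE_LEADERBOARD = pd.DataFrame(
    [
        ("CUHKMED",     1.75, 0.8826, 2,  0.9602, 2,  0.0450, 2),
        ("Masker",      2.50, 0.8837, 1,  0.9464, 8,  0.0414, 1),
        ("BUCT",        3.00, 0.8728, 4,  0.9525, 4,  0.0456, 3),
        ("ours",        4.10, 0.8786, 3,  0.9628, 1,  0.0520, 7),
        ("NKSG",        4.60, 0.8643, 6,  0.9488, 6,  0.0465, 4),
        ("VRT",         5.40, 0.8600, 7,  0.9532, 3,  0.0525, 8),
        ("AIML",        5.45, 0.8519, 8,  0.9505, 5,  0.0469, 5),
        ("Mammoth",     7.10, 0.8667, 5,  0.9361, 11, 0.0526, 9),
        ("SMILEDeepDR", 7.45, 0.8367, 9,  0.9386, 10, 0.0488, 6),
        ("NIGHTOwl",    8.60, 0.8257, 11, 0.9487, 7,  0.0563, 10),
        ("SDSAIRC",     9.15, 0.8315, 10, 0.9436, 9,  0.0674, 11),
        ("Cvblab",      11.00, 0.7728, 12, 0.9077, 12, 0.0798, 12),
        ("Winter_Fell", 12.00, 0.6861, 13, 0.8772, 13, 0.1536, 13),
    ],
    columns=["team", "score", "dsc_cup", "rank_cup", "dsc_disc", "rank_disc", "delta", "rank_delta"],
)

ABLATION_TABLE = pd.DataFrame(
    [
        # cae, bmal, db_plus, dsc_cup, dsc_disc, delta
        (False, False, False, 0.8427, 0.9387, 0.0785),
        (True,  False, False, 0.8526, 0.9425, 0.0702),
        (False, True,  False, 0.8652, 0.9514, 0.0721),
        (True,  True,  False, 0.8725, 0.9610, 0.0562),
        (True,  True,  True,  0.8786, 0.9628, 0.0520),
    ],
    columns=["cae", "bmal", "db_plus", "dsc_cup", "dsc_disc", "delta"],
)


def delta_margin(dataset: str) -> float:
    """CDR-error improvement of the proposed method over the best δ-reporting
    baseline on one cross-domain dataset ('drishti' or 'rimone')."""
    col = f"{dataset}_delta"
    if col not in CROSS_DOMAIN_TABLE:
        raise KeyError(f"unknown dataset {dataset!r}")
    ours = float(CROSS_DOMAIN_TABLE.loc[CROSS_DOMAIN_TABLE.method == "ours", col].iloc[0])
    others = CROSS_DOMAIN_TABLE.loc[CROSS_DOMAIN_TABLE.method != "ours", col].dropna()
    return float(others.min() - ours)


def disc_dsc_margin() -> float:
    """Disc-DSC lead of the proposed entry over the best other team on the
    challenge leaderboard."""
    ours = float(REFUGE_LEADERBOARD.loc[REFUGE_LEADERBOARD.team == "ours", "dsc_disc"].iloc[0])
    best_other = float(REFUGE_LEADERBOARD.loc[REFUGE_LEADERBOARD.team != "ours", "dsc_disc"].max())
    return ours - best_other


def ablation_delta_reduction() -> float:
    """δ reduction from adding autoencoder augmentation to the adversarial
    configuration (BMAL-only row minus CAE+BMAL row)."""
    t = ABLATION_TABLE
    bmal_only = float(t.loc[~t.cae & t.bmal & ~t.db_plus, "delta"].iloc[0])
    cae_bmal = float(t.loc[t.cae & t.bmal & ~t.db_plus, "delta"].iloc[0])
    return bmal_only - cae_bmal
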
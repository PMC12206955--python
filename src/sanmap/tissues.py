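"""Tissue classes and relaxation-parameter tables for the SAN-in-myocardium phantom.

The phantom distinguishes four regions: a signal-free background (the samples
are immersed in perfluoropolyether, which gives no proton signal), remote
myocardium, the sinoatrial node (SAN), and the epicardial fibrotic layer.
Reference relaxation times and magnetization-transfer ratios for SAN and
myocardium are the published ex vivo swine-heart means at 7 T and 3 T; the
epicardial layer, for which no measured values are tabulated, is assigned
synthetic values consistent with its higher fibrotic content than the SAN
(longer relaxation times, lower MTR).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import IntEnum

import numpy as np

__all__ = [
    "Tissue",
    "TissueParams",
    "tissue_table",
    "tissue_sd_table",
    "fibrosis_fractions",
    "jitter_tissue_table",
]


class Tissue(IntEnum):
    """Label vocabulary of the phantom."""

    BACKGROUND = 0
    MYOCARDIUM = 1
    SAN = 2
    EPICARDIUM = 3  # epicardial fibrotic layer


@dataclass(frozen=True)
class TissueParams:
    """Per-class relaxation parameters.

    Times are in milliseconds, ``mtr`` in percent, ``s0`` is the relative
    proton density (arbitrary units).
    """

    class_id: Tissue
    t_raff2: float
    t1rho: float
    t2: float
    t1: float
    mtr: float
    s0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("t_raff2", "t1rho", "t2", "t1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 <= self.mtr <= 100.0:
            raise ValueError(f"mtr must be in [0, 100], got {self.mtr}")
        if self.s0 < 0:
            raise ValueError(f"s0 must be >= 0, got {self.s0}")


# Published cohort means (SAN, myocardium) plus synthetic epicardial-layer values.
_TABLE_7T = {
    Tissue.BACKGROUND: TissueParams(Tissue.BACKGROUND, 1.0, 1.0, 1.0, 1.0, 0.0, s0=0.0),
    Tissue.MYOCARDIUM: TissueParams(Tissue.MYOCARDIUM, 90.0, 43.0, 36.0, 1166.0, 47.0),
    Tissue.SAN: TissueParams(Tissue.SAN, 124.0, 60.0, 47.0, 1322.0, 36.0),
    Tissue.EPICARDIUM: TissueParams(Tissue.EPICARDIUM, 170.0, 85.0, 65.0, 1500.0, 26.0),
}

_TABLE_3T = {
    Tissue.BACKGROUND: TissueParams(Tissue.BACKGROUND, 1.0, 1.0, 1.0, 1.0, 0.0, s0=0.0),
    Tissue.MYOCARDIUM: TissueParams(Tissue.MYOCARDIUM, 130.0, 75.0, 60.0, 945.0, 67.0),
    Tissue.SAN: TissueParams(Tissue.SAN, 193.0, 113.0, 97.0, 1074.0, 56.0),
    Tissue.EPICARDIUM: TissueParams(Tissue.EPICARDIUM, 260.0, 155.0, 135.0, 1250.0, 44.0),
}

# Published cohort standard deviations (epicardial layer mirrors the SAN spread).
_SD_7T = {
    Tissue.MYOCARDIUM: TissueParams(Tissue.MYOCARDIUM, 8.0, 5.0, 7.0, 79.0, 6.0, s0=0.0),
    Tissue.SAN: TissueParams(Tissue.SAN, 15.0, 10.0, 7.0, 106.0, 5.0, s0=0.0),
    Tissue.EPICARDIUM: TissueParams(Tissue.EPICARDIUM, 15.0, 10.0, 7.0, 106.0, 5.0, s0=0.0),
}

_SD_3T = {
    Tissue.MYOCARDIUM: TissueParams(Tissue.MYOCARDIUM, 3.0, 3.0, 8.0, 78.0, 7.0, s0=0.0),
    Tissue.SAN: TissueParams(Tissue.SAN, 13.0, 6.0, 16.0, 117.0, 6.0, s0=0.0),
    Tissue.EPICARDIUM: TissueParams(Tissue.EPICARDIUM, 13.0, 6.0, 16.0, 117.0, 6.0, s0=0.0),
}

#: Fibrotic (collagen) volume fraction per class used to render synthetic
#: histology: ~74% for the swine SAN, low for healthy myocardium, near-pure
#: collagen in the epicardial fibrotic layer, none in the signal-free
#: background.
FIBROSIS_FRACTIONS = {
    Tissue.BACKGROUND: 0.0,
    Tissue.MYOCARDIUM: 0.10,
    Tissue.SAN: 0.74,
    Tissue.EPICARDIUM: 0.95,
}


def _check_field(field: str) -> str:
    field = field.upper()
    if field not in ("7T", "3T"):
        raise ValueError(f"unknown field strength {field!r}; expected '7T' or '3T'")
    return field


def tissue_table(field: str = "7T") -> dict[Tissue, TissueParams]:
    """Default tissue parameters (class means) for a field strength."""
    return dict(_TABLE_7T if _check_field(field) == "7T" else _TABLE_3T)


def tissue_sd_table(field: str = "7T") -> dict[Tissue, TissueParams]:
    """Across-sample standard deviations of the tissue parameters."""
    return dict(_SD_7T if _check_field(field) == "7T" else _SD_3T)


def fibrosis_fractions() -> dict[Tissue, float]:
    return dict(FIBROSIS_FRACTIONS)


def jitter_tissue_table(
    table: dict[Tissue, TissueParams],
    sds: dict[Tissue, TissueParams],
    rng: np.random.Generator,
    shared_rho: float = 0.9,
) -> dict[Tissue, TissueParams]:
    """Draw one simulated heart's tissue parameters.

    Each parameter gets Gaussian jitter with the across-sample SD of its
    class, built from a heart-level factor shared by all tissue classes
    (weight ``shared_rho``) plus an independent class-specific component.
    The shared factor reflects that a heart that relaxes slowly does so in
    all its tissues: the published per-heart contrast SDs (e.g. 0.06 for the
    RAFF2 relaxation-time contrast, against ~0.15 implied by independent
    draws from the same tables) require strongly correlated SAN and
    myocardium times within a heart. Values are truncated so times stay
    positive and MTR stays in [0, 100].
    """
    if not 0.0 <= shared_rho <= 1.0:
        raise ValueError("shared_rho must be in [0, 1]")
    indep_w = float(np.sqrt(1.0 - shared_rho**2))
    # one shared heart-level draw per parameter kind
    shared = {name: rng.standard_normal() for name in ("t_raff2", "t1rho", "t2", "t1", "mtr")}
    out: dict[Tissue, TissueParams] = {}
    for cls, p in table.items():
        sd = sds.get(cls)
        if sd is None:
            out[cls] = p
            continue
        draws = {}
        for name in ("t_raff2", "t1rho", "t2", "t1", "mtr"):
            mu = getattr(p, name)
            s = getattr(sd, name)
            z = shared_rho * shared[name] + indep_w * rng.standard_normal()
            v = mu + s * z if s > 0 else mu
            if name == "mtr":
                v = float(np.clip(v, 0.0, 100.0))
            else:
                v = max(v, 0.05 * mu)  # keep times physical
            draws[name] = float(v)
        out[cls] = replace(p, **draws)
    return out
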
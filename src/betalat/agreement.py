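"""Categorical agreement between modalities and spatial peak comparison.

Language-dominance categories from MEG, fMRI and the Wada test are compared
with percent agreement, unweighted Cohen's kappa (chance-corrected via the
marginal products) and, for 2x2 tables, the Matthews correlation
coefficient. Kappa significance is assessed by a label permutation test;
a Bonferroni-style correction across the three ROIs multiplies p by 3
(capped at 1 by default, uncapped available).

Spatial agreement between two statistic maps is the Euclidean distance
between the maximum-statistic voxel coordinates within an ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .core import InvalidInputError, InvalidParameterError, SourceStatMap
from .laterality import ROIDefinition


@dataclass(frozen=True)
class LabelSeries:
    """Aligned per-subject categories from one modality."""

    subjects: tuple
    categories: tuple
    alphabet: tuple
    modality: str = ""

    def __post_init__(self) -> None:
        if len(self.subjects) != len(self.categories):
            raise InvalidInputError("subjects and categories differ in length")
        bad = set(self.categories) - set(self.alphabet)
        if bad:
            raise InvalidInputError(f"categories {sorted(bad)} outside alphabet")

    @property
    def n(self) -> int:
        return len(self.subjects)


def _aligned(a: LabelSeries, b: LabelSeries) -> tuple[np.ndarray, np.ndarray, list]:
    if a.subjects != b.subjects:
        raise InvalidInputError("series must share the same subjects in order")
    if set(a.alphabet) != set(b.alphabet):
        raise InvalidInputError("series must share a category alphabet")
    alphabet = list(a.alphabet)
    ai = np.array([alphabet.index(c) for c in a.categories])
    bi = np.array([alphabet.index(c) for c in b.categories])
    return ai, bi, alphabet


def contingency_table(a: LabelSeries, b: LabelSeries) -> pd.DataFrame:
    ai, bi, alphabet = _aligned(a, b)
    k = len(alphabet)
    table = np.zeros((k, k), int)
    np.add.at(table, (ai, bi), 1)
    return pd.DataFrame(table, index=pd.Index(alphabet, name=a.modality or "a"),
                        columns=pd.Index(alphabet, name=b.modality or "b"))


def percent_agreement(a: LabelSeries, b: LabelSeries) -> float:
    """Fraction of subjects with identical categories."""
    ai, bi, _ = _aligned(a, b)
    return float(np.mean(ai == bi))


def _kappa_from_table(table: np.ndarray) -> tuple[float, bool]:
    n = table.sum()
    po = np.trace(table) / n
    pe = float(np.sum(table.sum(axis=0) * table.sum(axis=1)) / n**2)
    if pe >= 1.0 - 1e-12:
        # both series constant and equal: perfect but chance-uncorrectable
        return 1.0, True
    return float((po - pe) / (1.0 - pe)), False


def cohen_kappa(
    a: LabelSeries,
    b: LabelSeries,
    n_perm: int = 0,
    seed: int = 0,
) -> tuple[float, float | None]:
    """Unweighted Cohen's kappa; optionally a one-sided permutation p-value
    (shuffling the second series, (b + 1)/(n_perm + 1) convention)."""
    ai, bi, alphabet = _aligned(a, b)
    k = len(alphabet)
    table = np.zeros((k, k), int)
    np.add.at(table, (ai, bi), 1)
    kappa, degenerate = _kappa_from_table(table)
    p: float | None = None
    if n_perm > 0 and not degenerate:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(bi)
            t = np.zeros((k, k), int)
            np.add.at(t, (ai, perm), 1)
            if _kappa_from_table(t)[0] >= kappa - 1e-12:
                count += 1
        p = (count + 1.0) / (n_perm + 1.0)
    elif n_perm > 0:
        p = 1.0 / (n_perm + 1.0)
    return kappa, p


def corrected_p(p: float, n_tests: int = 3, cap: bool = True) -> float:
    """Bonferroni-style multiplication across ROIs (capped at 1 by default)."""
    out = p * n_tests
    return min(out, 1.0) if cap else out


def matthews_cc(table: Sequence[Sequence[float]]) -> float:
    """Matthews correlation of a 2x2 contingency table ``[[TP, FN], [FP, TN]]``.

    Returns 0 when any margin is zero (the conventional degenerate value).
    """
    t = np.asarray(table, float)
    if t.shape != (2, 2):
        raise InvalidInputError("MCC requires a 2x2 table")
    if np.any(t < 0):
        raise InvalidInputError("counts must be non-negative")
    tp, fn = t[0]
    fp, tn = t[1]
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


@dataclass
class AgreementReport:
    """Agreement statistics between two aligned label series."""

    table: pd.DataFrame
    percent_agreement: float
    kappa: float
    kappa_p: float | None
    mcc: float | None
    n: int
    labels: tuple
    info: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "n": self.n,
            "percent_agreement": self.percent_agreement,
            "kappa": self.kappa,
            "kappa_p": self.kappa_p,
            "mcc": self.mcc,
            "table": self.table.to_dict(),
            **self.info,
        }


def agreement_report(a: LabelSeries, b: LabelSeries, n_perm: int = 10_000,
                     seed: int = 0) -> AgreementReport:
    """Full agreement report; MCC only for two-category alphabets."""
    table = contingency_table(a, b)
    kappa, p = cohen_kappa(a, b, n_perm=n_perm, seed=seed)
    mcc = matthews_cc(table.values) if table.shape == (2, 2) else None
    return AgreementReport(
        table=table, percent_agreement=percent_agreement(a, b),
        kappa=kappa, kappa_p=p, mcc=mcc, n=a.n, labels=tuple(a.alphabet),
        info={"modalities": (a.modality, b.modality)},
    )


def peak_coordinate(stat_map: SourceStatMap, roi: ROIDefinition,
                    side: str = "both") -> np.ndarray | None:
    """Coordinates (mm) of the maximum-statistic voxel within an ROI side.

    Only surviving (nonzero, evaluated) voxels count; ties are broken by the
    lowest voxel index. Returns ``None`` when the ROI holds no surviving
    voxel ("no-peak").
    """
    labels = stat_map.grid.atlas_labels
    if side == "left":
        wanted = roi.left_labels
    elif side == "right":
        wanted = roi.right_labels
    elif side == "both":
        wanted = roi.left_labels | roi.right_labels
    else:
        raise InvalidParameterError("side must be 'left', 'right' or 'both'")
    sel = np.isin(labels, list(wanted)) & stat_map.mask & (stat_map.values > 0)
    if not sel.any():
        return None
    idx = np.flatnonzero(sel)
    best = idx[np.argmax(stat_map.values[idx])]  # argmax: first max -> lowest index
    return stat_map.grid.positions[best].copy()


def euclidean_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Plain L2 distance (mm) between two peak coordinates."""
    return float(np.linalg.norm(np.asarray(p, float) - np.asarray(q, float)))
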
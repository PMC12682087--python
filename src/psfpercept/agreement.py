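"""Likert feature-assessment analysis: consensus vectors and 2x2 association.

Raters score each image against a fixed catalog of 13 feature descriptors on
a 5-point agreement scale. Per image, responses collapse to a binary
consensus vector (bit set when strictly more than 50% of raters chose Agree
or Strongly Agree). Pairs of consensus vectors are compared with Yule's Q
plus sensitivity metrics (Phi, Cohen's kappa, mutual information).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

N_DESCRIPTORS = 13

_REQUIRED_COLUMNS = ("rater_id", "image_id", "descriptor_index", "response")


def descriptor_catalog() -> list[str]:
    """The ordered 13-descriptor catalog shipped with the package."""
    payload = json.loads(
        resources.files("psfpercept.data").joinpath("descriptors.json").read_text()
    )
    descriptors = payload["descriptors"]
    assert len(descriptors) == N_DESCRIPTORS
    return descriptors


@dataclass
class LikertResponseSet:
    """Long-format ordinal responses: one row per (rater, image, descriptor).

    ``image_type`` tags the whole set as responses to drawn or geometric
    stimuli. Missing cells are simply absent rows — never NaN.
    """

    responses: pd.DataFrame
    image_type: str = "drawn"

    def __post_init__(self) -> None:
        df = self.responses
        missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"response table missing columns: {missing}")
        if self.image_type not in ("drawn", "geometric"):
            raise ValueError(f"unknown image_type {self.image_type!r}")
        resp = df["response"]
        if not resp.between(1, 5).all():
            bad = df.loc[~resp.between(1, 5)]
            raise ValueError(
                f"responses outside 1..5 at rows {list(bad.index[:5])}"
            )
        didx = df["descriptor_index"]
        if not didx.between(0, N_DESCRIPTORS - 1).all():
            raise ValueError("descriptor_index outside 0..12")
        if df.duplicated(["rater_id", "image_id", "descriptor_index"]).any():
            raise ValueError("duplicate (rater, image, descriptor) responses")

    @property
    def image_ids(self) -> list:
        return sorted(self.responses["image_id"].unique().tolist())


@dataclass(frozen=True)
class ConsensusVector:
    """Per-image binary feature vector plus the agree fractions behind it."""

    bits: np.ndarray
    agree_fraction: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=int)
        frac = np.asarray(self.agree_fraction, dtype=float)
        if bits.shape != (N_DESCRIPTORS,) or frac.shape != (N_DESCRIPTORS,):
            raise ValueError(f"consensus vector must have length {N_DESCRIPTORS}")
        expected = (frac > 0.5).astype(int)
        if not np.array_equal(bits, expected):
            raise ValueError("bits inconsistent with agree fractions (> 0.5 rule)")
        object.__setattr__(self, "bits", bits)
        object.__setattr__(self, "agree_fraction", frac)


@dataclass
class AssociationResult:
    """Association metrics for one 2x2 table (a, b, c, d).

    ``phi``/``kappa``/``p_value`` are ``None`` when undefined (zero
    marginal or empty table cell where required), never silently zero.
    """

    table: tuple[int, int, int, int]
    q: float | None
    phi: float | None
    kappa: float | None
    mi_bits: float
    p_value: float | None = None


def consensus_vector(responses: LikertResponseSet, image_id) -> ConsensusVector:
    """Collapse one image's Likert responses to a 13-bit consensus vector.

    Per descriptor, the fraction of non-missing raters answering 4 or 5 is
    computed; the bit is 1 iff that fraction strictly exceeds 0.5.
    """
    df = responses.responses
    sub = df[df["image_id"] == image_id]
    if sub.empty:
        raise ValueError(f"no responses for image {image_id!r}")
    frac = np.full(N_DESCRIPTORS, np.nan)
    for d in range(N_DESCRIPTORS):
        vals = sub.loc[sub["descriptor_index"] == d, "response"]
        if vals.empty:
            raise ValueError(
                f"descriptor {d} has zero responses for image {image_id!r}"
            )
        frac[d] = (vals >= 4).mean()
    bits = (frac > 0.5).astype(int)
    return ConsensusVector(bits=bits, agree_fraction=frac)


# ---------------------------------------------------------------------------
# 2x2 association metrics
# ---------------------------------------------------------------------------


def contingency_table(
    va: ConsensusVector, vb: ConsensusVector
) -> tuple[int, int, int, int]:
    a = int(np.sum((va.bits == 1) & (vb.bits == 1)))
    b = int(np.sum((va.bits == 1) & (vb.bits == 0)))
    c = int(np.sum((va.bits == 0) & (vb.bits == 1)))
    d = int(np.sum((va.bits == 0) & (vb.bits == 0)))
    return a, b, c, d


def yules_q_from_table(table: tuple[int, int, int, int]) -> float:
    """Q = (ad - bc)/(ad + bc) with the signed-limit convention when a
    product vanishes: +1 if bc = 0 < ad, -1 if ad = 0 < bc; both zero is
    undefined and raises."""
    a, b, c, d = table
    ad, bc = a * d, b * c
    if ad + bc == 0:
        if ad == 0 and bc == 0:
            raise ValueError(f"Yule's Q undefined for table {table} (ad = bc = 0)")
    if bc == 0 and ad > 0:
        return 1.0
    if ad == 0 and bc > 0:
        return -1.0
    return (ad - bc) / (ad + bc)


def phi_from_table(table: tuple[int, int, int, int]) -> float | None:
    a, b, c, d = table
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return None
    return (a * d - b * c) / math.sqrt(denom)


def kappa_from_table(table: tuple[int, int, int, int]) -> float | None:
    a, b, c, d = table
    n = a + b + c + d
    # a zero marginal leaves chance-corrected agreement undefined
    if min(a + b, c + d, a + c, b + d) == 0:
        return None
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    if pe == 1.0:
        return None
    return (po - pe) / (1.0 - pe)


def mutual_information_bits(table: tuple[int, int, int, int]) -> float:
    """Mutual information (base-2) of the empirical joint distribution."""
    a, b, c, d = table
    n = a + b + c + d
    joint = np.array([[a, b], [c, d]], dtype=float) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mi = 0.0
    for i in range(2):
        for j in range(2):
            if joint[i, j] > 0:
                mi += joint[i, j] * math.log2(joint[i, j] / (px[i] * py[j]))
    return max(mi, 0.0)


def q_p_value(table: tuple[int, int, int, int]) -> float | None:
    """Two-sided p-value for Q != 0 from the large-sample SE of Yule's Q.

    SE(Q) = (1 - Q^2)/2 * sqrt(1/a + 1/b + 1/c + 1/d); undefined (None)
    when any cell is empty.
    """
    a, b, c, d = table
    if min(a, b, c, d) == 0:
        return None
    q = yules_q_from_table(table)
    se = (1.0 - q * q) / 2.0 * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    if se == 0:
        return None
    z = q / se
    return float(2.0 * stats.norm.sf(abs(z)))


def yules_q(va: ConsensusVector, vb: ConsensusVector) -> AssociationResult:
    """Yule's Q (plus companion metrics) for two consensus vectors; raises
    on a fully degenerate table (ad = bc = 0)."""
    table = contingency_table(va, vb)
    result = association_suite_from_table(table)
    if result.q is None:
        raise ValueError(f"Yule's Q undefined for table {table} (ad = bc = 0)")
    return result


def association_suite(va: ConsensusVector, vb: ConsensusVector) -> AssociationResult:
    """All four association metrics on the same 2x2 table; degenerate
    metrics come back as None (missing), never as zero."""
    return association_suite_from_table(contingency_table(va, vb))


def association_suite_from_table(
    table: tuple[int, int, int, int]
) -> AssociationResult:
    try:
        q = yules_q_from_table(table)
    except ValueError:
        q = None
    return AssociationResult(
        table=table,
        q=q,
        phi=phi_from_table(table),
        kappa=kappa_from_table(table),
        mi_bits=mutual_information_bits(table),
        p_value=q_p_value(table),
    )


# ---------------------------------------------------------------------------
# Study-level aggregation
# ---------------------------------------------------------------------------


@dataclass
class ConsensusStudyResult:
    per_pair: list[AssociationResult]
    image_ids: list
    q_summary: dict
    metric_correlations: pd.DataFrame
    metric_p_values: pd.DataFrame


def consensus_study(
    drawn: LikertResponseSet, geometric: LikertResponseSet
) -> ConsensusStudyResult:
    """Pairwise association between drawn and geometric consensus vectors.

    One AssociationResult per image pair, a summary of Q (mean, SD, min,
    max) and the Pearson correlation matrix between the four metrics across
    pairs (pairs where a metric is undefined are dropped pairwise).
    """
    ids_d = drawn.image_ids
    ids_g = geometric.image_ids
    if ids_d != ids_g:
        raise ValueError(
            f"image-pair index sets differ: drawn {ids_d} vs geometric {ids_g}"
        )
    results = []
    for image_id in ids_d:
        va = consensus_vector(drawn, image_id)
        vb = consensus_vector(geometric, image_id)
        results.append(association_suite(va, vb))
    qs = np.array([r.q for r in results if r.q is not None])
    if len(qs) == 0:
        raise ValueError("Yule's Q undefined for every image pair")
    q_summary = {
        "mean": float(qs.mean()),
        "sd": float(qs.std(ddof=1)) if len(qs) > 1 else 0.0,
        "min": float(qs.min()),
        "max": float(qs.max()),
        "n_pairs": len(results),
    }
    metrics = pd.DataFrame(
        {
            "q": [r.q for r in results],
            "phi": [r.phi if r.phi is not None else np.nan for r in results],
            "kappa": [r.kappa if r.kappa is not None else np.nan for r in results],
            "mi_bits": [r.mi_bits for r in results],
        }
    )
    names = list(metrics.columns)
    corr = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    pvals = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    for i, mi_name in enumerate(names):
        for j, mj_name in enumerate(names):
            if i >= j:
                continue
            sub = metrics[[mi_name, mj_name]].dropna()
            if len(sub) < 3 or sub[mi_name].std() == 0 or sub[mj_name].std() == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(sub[mi_name], sub[mj_name])
            corr.iloc[i, j] = corr.iloc[j, i] = r
            pvals.iloc[i, j] = pvals.iloc[j, i] = p
    return ConsensusStudyResult(
        per_pair=results,
        image_ids=ids_d,
        q_summary=q_summary,
        metric_correlations=corr,
        metric_p_values=pvals,
    )


def likert_distribution_summary(
    responses: LikertResponseSet, image_id
) -> pd.DataFrame:
    """Combined %disagree / %neutral / %agree per descriptor, ordered by
    %agree descending with ties broken by descriptor index."""
    df = responses.responses
    sub = df[df["image_id"] == image_id]
    if sub.empty:
        raise ValueError(f"no responses for image {image_id!r}")
    rows = []
    for d in range(N_DESCRIPTORS):
        vals = sub.loc[sub["descriptor_index"] == d, "response"]
        if vals.empty:
            raise ValueError(f"descriptor {d} has zero responses")
        n = len(vals)
        rows.append(
            {
                "descriptor_index": d,
                "pct_disagree": 100.0 * (vals <= 2).sum() / n,
                "pct_neutral": 100.0 * (vals == 3).sum() / n,
                "pct_agree": 100.0 * (vals >= 4).sum() / n,
            }
        )
    out = pd.DataFrame(rows)
    out = out.sort_values(
        ["pct_agree", "descriptor_index"], ascending=[False, True]
    ).reset_index(drop=True)
    return out
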
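"""Human-coded depiction-style labels and inter-rater agreement.

Depiction styles — facial expressions, body language, symbolic
representation, narrative illustration (tangible) and ambiguous/abstract
expression — are judgments made by trained human raters; they are never
computed from pixels. This module ingests the label tables, quantifies
rater agreement (Cohen's kappa pairwise, Fleiss' kappa for three or more
raters, plus raw percent agreement, reported separately and never
conflated), and tabulates per-emotion prevalence.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.inter_rater import aggregate_raters, fleiss_kappa

__all__ = [
    "STYLE_CATEGORIES",
    "StyleLabels",
    "KappaReport",
    "read_annotations",
    "annotations_frame",
    "cohen_kappa",
    "inter_rater_kappa",
    "style_prevalence",
]

#: The five binary depiction-style indicators.
STYLE_CATEGORIES: tuple[str, ...] = (
    "facial",
    "body",
    "symbolic",
    "narrative",
    "abstract",
)


@dataclass(frozen=True)
class StyleLabels:
    """Five 0/1 style indicators for one drawing.

    Tangible indicators may co-occur (a drawing can show a face and a
    symbol); ``abstract`` marks ambiguous, non-obvious depictions.
    """

    source_id: str
    facial: int
    body: int
    symbolic: int
    narrative: int
    abstract: int

    def __post_init__(self) -> None:
        for cat in STYLE_CATEGORIES:
            v = getattr(self, cat)
            if v not in (0, 1):
                raise ValueError(
                    f"{self.source_id}: {cat} must be 0 or 1, got {v!r}"
                )


def read_annotations(path: str | Path) -> list[StyleLabels]:
    """Read a style-label CSV with header source_id,facial,body,symbolic,narrative,abstract."""
    try:
        df = pd.read_csv(path, dtype={"source_id": str})
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    expected = ["source_id", *STYLE_CATEGORIES]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"annotation CSV {path!s} missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            StyleLabels(
                source_id=str(row["source_id"]),
                **{c: int(row[c]) for c in STYLE_CATEGORIES},
            )
        )
    return out


def annotations_frame(labels: list[StyleLabels]) -> pd.DataFrame:
    """Labels as a DataFrame indexed by source_id."""
    if not labels:
        return pd.DataFrame(columns=list(STYLE_CATEGORIES)).rename_axis("source_id")
    df = pd.DataFrame([l.__dict__ for l in labels]).set_index("source_id")
    return df[list(STYLE_CATEGORIES)]


@dataclass
class KappaReport:
    """Agreement summary for one rater table.

    ``fleiss`` is None for two raters; any kappa is None (with
    ``degenerate`` True) when every rater gave a single constant code,
    which leaves chance agreement undefined.
    """

    pairwise_cohen: dict[tuple[str, str], float | None]
    fleiss: float | None
    percent_agreement: float
    degenerate: bool

    @property
    def overall(self) -> float | None:
        if self.fleiss is not None:
            return self.fleiss
        vals = [v for v in self.pairwise_cohen.values() if v is not None]
        return float(np.mean(vals)) if vals else None


def cohen_kappa(a: pd.Series | np.ndarray, b: pd.Series | np.ndarray) -> float | None:
    """Cohen's kappa between two raters; None if chance agreement is 1."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length rating vectors with >= 2 items")
    cats = sorted(set(a) | set(b), key=str)
    idx = {c: i for i, c in enumerate(cats)}
    k = len(cats)
    table = np.zeros((k, k))
    for x, y in zip(a, b):
        table[idx[x], idx[y]] += 1
    n = table.sum()
    po = np.trace(table) / n
    pe = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    if pe >= 1.0 - 1e-12:
        return None
    return float((po - pe) / (1.0 - pe))


def inter_rater_kappa(table: pd.DataFrame) -> KappaReport:
    """Agreement for a rater table (rows = drawings, columns = raters).

    Two raters: Cohen's kappa. Three or more: Fleiss' kappa plus all
    pairwise Cohen's kappas. Percent agreement is the share of items on
    which every rater gave the same code.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least two raters")
    if table.shape[0] < 2:
        raise ValueError("need at least two rated items")
    raters = list(table.columns)
    pairwise = {
        (str(r1), str(r2)): cohen_kappa(table[r1], table[r2])
        for r1, r2 in itertools.combinations(raters, 2)
    }
    all_same = table.nunique(axis=1).eq(1)
    percent_agreement = float(100.0 * all_same.mean())
    constant = table.stack().nunique() == 1
    fk: float | None = None
    if len(raters) >= 3 and not constant:
        counts, _ = aggregate_raters(table.to_numpy())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fk = float(fleiss_kappa(counts, method="fleiss"))
        if not np.isfinite(fk):
            fk = None
    degenerate = constant or all(v is None for v in pairwise.values())
    return KappaReport(
        pairwise_cohen=pairwise,
        fleiss=fk,
        percent_agreement=percent_agreement,
        degenerate=degenerate,
    )


def style_prevalence(
    labels: pd.DataFrame, emotions: pd.Series
) -> pd.DataFrame:
    """Per-emotion percentage of drawings carrying each style indicator.

    ``labels``: DataFrame indexed by source_id with the five 0/1 style
    columns. ``emotions``: Series mapping source_id to emotion name.
    Columns sum to more than 100 when tangible styles co-occur.
    """
    emotions = emotions.reindex(labels.index)
    unknown = emotions.isna()
    if unknown.any():
        warnings.warn(
            f"dropping {int(unknown.sum())} labels with no matching emotion",
            stacklevel=2,
        )
    joined = labels.loc[~unknown].copy()
    joined["emotion"] = emotions[~unknown]
    prev = joined.groupby("emotion")[list(STYLE_CATEGORIES)].mean() * 100.0
    return prev.T
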
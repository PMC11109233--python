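"""End-to-end orchestration: extract features, join labels, analyse, report.

The report bundle mirrors the study's result tables: a per-emotion
composition comparison (means, SDs, one-way ANOVA F and p per metric),
a prominent-color distribution with its chi-square test, a style
prevalence table, the multinomial-logit model report and the
observed-by-predicted classification table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import emotion_stats as es
from .color_features import BlankCanvasError, FeatureVector, extract_features
from .image_io import ImageDecodeError, load_image
from .palette import EXPRESSIVE_COLORS, ColorPalette
from .style_annotations import STYLE_CATEGORIES, style_prevalence

__all__ = [
    "emotion_from_source_id",
    "extract_directory",
    "features_frame",
    "composition_table",
    "prominent_table",
    "ReportBundle",
    "analyze",
]

_METRICS = [
    *[f"pct_{c}" for c in EXPRESSIVE_COLORS],
    "n_colors",
    "saturation_pct",
    "brightness_pct",
    "color_fill_pct",
    "image_coverage_pct",
]


def emotion_from_source_id(source_id: str) -> str | None:
    """Emotion label from a ``{participant}_{emotion}`` id, else None.

    Labels come from the naming convention (the drawing task assigns the
    emotion); they are never inferred from image content.
    """
    tail = source_id.rsplit("_", 1)[-1].lower()
    return tail if tail in es.EMOTIONS else None


def features_frame(features: list[FeatureVector]) -> pd.DataFrame:
    """Feature vectors as a DataFrame indexed by source_id, with emotion."""
    df = pd.DataFrame([f.as_row() for f in features]).set_index("source_id")
    df.insert(0, "emotion", [emotion_from_source_id(i) for i in df.index])
    return df


def extract_directory(
    input_dir: str | Path,
    palette: ColorPalette | None = None,
    *,
    min_share: float = 1.0,
    connectivity: int = 1,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Extract features for every readable image in a directory.

    Returns (features frame, rejects) where rejects lists (filename,
    reason) for unreadable or blank images, mirroring the study's
    removal of unreadable or incorrect submissions.
    """
    input_dir = Path(input_dir)
    paths = sorted(
        p for p in input_dir.iterdir()
        if p.suffix.lower() in (".png", ".jpg", ".jpeg")
    )
    if not paths:
        raise FileNotFoundError(f"no images found in {input_dir!s}")
    feats: list[FeatureVector] = []
    rejects: list[tuple[str, str]] = []
    for p in paths:
        try:
            img = load_image(p)
            feats.append(
                extract_features(
                    img, palette, min_share=min_share, connectivity=connectivity
                )
            )
        except (ImageDecodeError, BlankCanvasError) as exc:
            rejects.append((p.name, str(exc)))
    if not feats:
        raise RuntimeError(f"no readable drawings in {input_dir!s}")
    return features_frame(feats), rejects


def composition_table(features: pd.DataFrame) -> pd.DataFrame:
    """Per-emotion mean (SD) of every metric plus one-way ANOVA F and p."""
    rows = []
    emotions = [e for e in es.EMOTIONS if (features["emotion"] == e).any()]
    for metric in _METRICS:
        groups = [
            features.loc[features["emotion"] == e, metric].to_numpy(dtype=float)
            for e in emotions
        ]
        row: dict[str, float | str] = {"metric": metric}
        for e, g in zip(emotions, groups):
            row[f"{e}_mean"] = float(np.mean(g))
            row[f"{e}_sd"] = float(np.std(g, ddof=1)) if len(g) > 1 else 0.0
        if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
            f, p = es.oneway_anova(groups)
            row["F"], row["p"] = f, p
        rows.append(row)
    return pd.DataFrame(rows).set_index("metric")


def prominent_table(features: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Prominent-color percentage per emotion, with the chi-square test."""
    counts = pd.crosstab(features["emotion"], features["prominent_color"])
    counts = counts.reindex(
        index=[e for e in es.EMOTIONS if e in counts.index],
        columns=[c for c in EXPRESSIVE_COLORS if c in counts.columns],
        fill_value=0,
    )
    pct = 100.0 * counts.div(counts.sum(axis=1), axis=0)
    test: dict = {}
    nonzero = counts.loc[:, counts.sum(axis=0) > 0]
    if nonzero.shape[0] >= 2 and nonzero.shape[1] >= 2:
        stat, dof, p = es.chisq_independence(nonzero)
        test = {"chi2": stat, "df": dof, "p": p}
    return pct, test


@dataclass
class ReportBundle:
    """All analysis outputs for one run."""

    composition: pd.DataFrame
    prominent_pct: pd.DataFrame
    prominent_test: dict
    styles: pd.DataFrame | None
    model: es.EmotionModel | None
    classification: es.ClassificationTable | None
    bootstrap_ci: pd.DataFrame | None
    bootstrap_failed: int
    seed: int
    palette_hash: str

    def model_report(self) -> dict:
        if self.model is None:
            return {}
        m = self.model
        return {
            "reference_emotion": m.reference,
            "n_obs": m.n_obs,
            "log_likelihood": m.log_likelihood,
            "null_log_likelihood": m.null_log_likelihood,
            "lr_chi2": m.lr_chi2,
            "lr_df": m.lr_df,
            "lr_pvalue": m.lr_pvalue,
            "nagelkerke_r2": m.nagelkerke_r2,
            "converged": m.converged,
            "n_iter": m.n_iter,
            "overall_percent_correct": (
                self.classification.overall_percent if self.classification else None
            ),
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.composition.to_csv(out / "composition_by_emotion.csv")
        self.prominent_pct.to_csv(out / "prominent_colors.csv")
        if self.styles is not None:
            self.styles.to_csv(out / "style_prevalence.csv")
        if self.model is not None:
            self.model.coefficients.to_csv(out / "model_coefficients.csv")
        if self.classification is not None:
            self.classification.table.to_csv(out / "classification_table.csv")
        if self.bootstrap_ci is not None:
            self.bootstrap_ci.to_csv(out / "bootstrap_intervals.csv")
        log = {
            "seed": self.seed,
            "palette_hash": self.palette_hash,
            "prominent_chisq": self.prominent_test,
            "bootstrap_failed": self.bootstrap_failed,
            **self.model_report(),
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str) + "\n")


def analyze(
    features: pd.DataFrame,
    styles: pd.DataFrame | None = None,
    *,
    reference: str = "happiness",
    bootstrap_B: int = 0,
    seed: int = 0,
    palette: ColorPalette | None = None,
    fit_model: bool = True,
) -> ReportBundle:
    """Run the full inferential stage on an extracted feature table."""
    palette = palette or ColorPalette()
    features = features.dropna(subset=["emotion"])
    if features.empty:
        raise ValueError("no rows with a recognised emotion label")
    comp = composition_table(features)
    prom_pct, prom_test = prominent_table(features)

    style_tab = None
    model = None
    ctab = None
    boot = None
    failed = 0
    use_styles = styles is not None and not styles.empty
    if styles is not None and not use_styles:
        warnings.warn("empty styles table: style-dependent outputs omitted",
                      stacklevel=2)
    if use_styles:
        style_tab = style_prevalence(
            styles, features["emotion"]
        )
    if fit_model and features["emotion"].nunique() >= 2:
        X, y = es.build_design_matrix(
            features, styles if use_styles else None
        )
        ref = reference if reference in set(y) else y.iloc[0]
        try:
            model = es.fit_multinomial_logit(X, y, reference=ref)
            ctab = es.classification_table(model, X, y)
            if bootstrap_B > 0:
                boot, failed = es.bootstrap_fit(
                    X, y, B=bootstrap_B, seed=seed, reference=ref
                )
        except (es.SeparationError, ValueError) as exc:
            warnings.warn(f"model withheld: {exc}", stacklevel=2)
    return ReportBundle(
        composition=comp,
        prominent_pct=prom_pct,
        prominent_test=prom_test,
        styles=style_tab,
        model=model,
        classification=ctab,
        bootstrap_ci=boot,
        bootstrap_failed=failed,
        seed=seed,
        palette_hash=palette.content_hash(),
    )
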
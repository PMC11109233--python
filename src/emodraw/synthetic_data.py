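"""Seeded synthetic emotion drawings with known ground truth.

Each emotion has a generating profile: per-color mean/SD of the
composition shares, a multinomial over prominent colors, mean/SD for
saturation, brightness, fill and coverage, and Bernoulli rates for the
five depiction-style labels. Default profiles reproduce the published
per-emotion statistics of the drawing study this package models (182
participants, four emotions each).

Sampling model
--------------
Compositions follow a two-component mixture that reproduces the
published prominence multinomial and per-color means simultaneously,
with dispersion close to the published SDs. Per drawing: the prominent
color is drawn from its multinomial; its share comes from a truncated
normal whose location is calibrated per color; the remaining mass is
split over the other colors proportionally to normals at the published
(mean, SD) clipped at zero, capped strictly below the prominent share.
Saturation, brightness, fill and coverage are truncated normals on
[0, 100] with coverage >= fill enforced by joint resampling. Styles are
independent Bernoullis.

Clipping, renormalisation, capping and the renderer's feasibility
projection all shift raw means, so the generator calibrates its location
parameters deterministically (an analytic linear system for the
conditional prominent-share means, refined by a damped Monte-Carlo
bias-correction loop on an internal fixed seed, independent of the
user's cohort seed) so that the *population mean of the achieved
features equals the profile means*. That property is the generator's
contract: a pipeline-extracted cohort mean is an unbiased estimate of
the corresponding profile value.

Rendering
---------
A drawing is a random star-shaped blob covering ``coverage`` percent of
the canvas, with an interior hole carved so the painted area is ``fill``
percent (the hole is kept off the blob boundary, so border flood-fill
cannot reach it and the coverage metric sees the full blob). Painted
pixels are partitioned among the colors by largest-remainder rounding of
the shares, and each color is painted with an HSV triple inside its
classification range, chosen by water-filling so the drawn-pixel mean S
and V hit the ground-truth saturation and brightness up to feasibility.
The achieved, pixel-exact ground truth is recomputed from the renderer's
own bookkeeping and returned alongside the image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_io import RasterImage, hsv_to_rgb_opencv, rgb_to_hsv_opencv, save_image
from .palette import EXPRESSIVE_COLORS, ColorPalette
from .style_annotations import STYLE_CATEGORIES

__all__ = [
    "EmotionProfile",
    "GroundTruth",
    "Cohort",
    "default_profiles",
    "sample_composition",
    "render_drawing",
    "generate_cohort",
]

_CAL_SEED = 723_182          # internal calibration stream, not user-facing
_CAL_BATCH = 20000
_CAL_ITER = 25
_CAL_DAMPING = 0.8

#: Safe interior HSV bounds per color: (s_lo, s_hi, v_lo, v_hi).
#: Kept 3 units inside the classification boxes (and clear of the black
#: V <= 70 precedence cut) so integer RGB round-trips cannot flip class.
_SV_BOUNDS: dict[str, tuple[int, int, int, int]] = {
    "red": (56, 255, 74, 255),
    "yellow": (49, 255, 74, 255),
    "green": (49, 255, 74, 255),
    "blue": (56, 255, 74, 255),
    "purple": (56, 255, 74, 255),
    "gray": (0, 22, 74, 226),
    "black": (0, 255, 0, 67),
}

#: Mid-range hue per color (OpenCV scale); achromatics use hue 0.
_HUES: dict[str, int] = {
    "red": 5,
    "yellow": 23,
    "green": 60,
    "blue": 104,
    "purple": 135,
    "gray": 0,
    "black": 0,
}


@dataclass(frozen=True)
class EmotionProfile:
    """Generating distribution for one emotion's drawings.

    ``color_mix`` maps color -> (mean share %, SD); ``prominent_probs``
    is a multinomial over the seven colors; the four scalar metrics are
    (mean, SD) pairs on the 0-100 scale; ``style_probs`` maps the five
    style categories to Bernoulli rates.
    """

    emotion: str
    color_mix: Mapping[str, tuple[float, float]]
    prominent_probs: Mapping[str, float]
    saturation: tuple[float, float]
    brightness: tuple[float, float]
    fill: tuple[float, float]
    coverage: tuple[float, float]
    style_probs: Mapping[str, float]

    def __post_init__(self) -> None:
        means = np.array([self.color_mix[c][0] for c in EXPRESSIVE_COLORS])
        sds = np.array([self.color_mix[c][1] for c in EXPRESSIVE_COLORS])
        if (means < 0).any() or (sds < 0).any():
            raise ValueError("color_mix means and SDs must be non-negative")
        if means.sum() <= 0:
            raise ValueError(f"{self.emotion}: degenerate all-zero color mix")
        pp = np.array([self.prominent_probs.get(c, 0.0) for c in EXPRESSIVE_COLORS])
        if (pp < 0).any() or not np.isclose(pp.sum(), 1.0, atol=1e-6):
            raise ValueError("prominent_probs must be a distribution over colors")
        for name in ("saturation", "brightness", "fill", "coverage"):
            m, s = getattr(self, name)
            if not (0.0 <= m <= 100.0) or s < 0:
                raise ValueError(f"{self.emotion}: invalid {name} profile ({m}, {s})")
        for cat, p in self.style_probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"invalid style probability {cat}={p}")

    # hashable key for the calibration cache
    def _key(self) -> tuple:
        return (
            self.emotion,
            tuple((c, *self.color_mix[c]) for c in EXPRESSIVE_COLORS),
            tuple(round(self.prominent_probs.get(c, 0.0), 12) for c in EXPRESSIVE_COLORS),
            self.saturation,
            self.brightness,
            self.fill,
            self.coverage,
            tuple((c, self.style_probs.get(c, 0.0)) for c in STYLE_CATEGORIES),
        )


@dataclass
class GroundTruth:
    """Intended (or achieved) feature values for one generated drawing."""

    source_id: str
    emotion: str
    shares: dict[str, float]           # per-color %, sums to 100
    prominent: str
    saturation: float
    brightness: float
    fill: float
    coverage: float
    styles: dict[str, int]

    def __post_init__(self) -> None:
        total = sum(self.shares.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"{self.source_id}: shares sum to {total}, not 100")
        if self.fill > self.coverage + 1e-9:
            raise ValueError(f"{self.source_id}: fill {self.fill} > coverage {self.coverage}")

    def as_row(self) -> dict:
        row: dict = {"source_id": self.source_id, "emotion": self.emotion}
        for c in EXPRESSIVE_COLORS:
            row[f"share_{c}"] = self.shares[c]
        row.update(
            prominent=self.prominent,
            saturation=self.saturation,
            brightness=self.brightness,
            fill=self.fill,
            coverage=self.coverage,
        )
        return row


# ---------------------------------------------------------------------------
# default profiles: the published per-emotion statistics
# ---------------------------------------------------------------------------

_COLOR_TABLE: dict[str, dict[str, tuple[float, float]]] = {
    "anger": {
        "red": (72.27, 35.72), "yellow": (5.1, 15.97), "green": (0.58, 5.65),
        "blue": (4.21, 17.92), "purple": (1.59, 10.85), "gray": (4.64, 17.37),
        "black": (11.61, 26.51),
    },
    "happiness": {
        "red": (21.92, 34.77), "yellow": (49.9, 44.21), "green": (7.65, 20.92),
        "blue": (6.29, 20.89), "purple": (1.81, 9.6), "gray": (3.34, 15.69),
        "black": (9.09, 25.01),
    },
    "sadness": {
        "red": (3.26, 14.86), "yellow": (4.44, 17.0), "green": (3.34, 15.58),
        "blue": (51.66, 44.32), "purple": (3.8, 16.7), "gray": (17.85, 34.34),
        "black": (15.65, 30.58),
    },
    "fear": {
        "red": (8.14, 22.44), "yellow": (4.2, 15.72), "green": (6.76, 22.55),
        "blue": (10.49, 26.89), "purple": (10.06, 27.64), "gray": (26.43, 39.9),
        "black": (33.92, 42.98),
    },
}

_SCALAR_TABLE: dict[str, dict[str, tuple[float, float]]] = {
    "anger": {
        "saturation": (65.62, 21.46), "brightness": (60.34, 17.46),
        "fill": (30.73, 18.45), "coverage": (87.17, 11.22),
    },
    "happiness": {
        "saturation": (68.52, 21.24), "brightness": (75.44, 14.93),
        "fill": (25.14, 15.3), "coverage": (87.23, 9.35),
    },
    "sadness": {
        "saturation": (63.94, 25.18), "brightness": (59.47, 18.21),
        "fill": (26.77, 19.28), "coverage": (85.38, 10.47),
    },
    "fear": {
        "saturation": (47.33, 32.46), "brightness": (48.78, 23.02),
        "fill": (35.49, 23.47), "coverage": (85.25, 12.67),
    },
}

#: Modal prominent-color share per emotion; the remaining probability
#: mass is spread over the other colors proportionally to their mean
#: composition shares.
_PROMINENT_MODES: dict[str, tuple[str, float]] = {
    "anger": ("red", 0.7311),
    "happiness": ("yellow", 0.478),
    "sadness": ("blue", 0.512),
    "fear": ("black", 0.407),
}

_STYLE_TABLE: dict[str, dict[str, float]] = {
    "anger": {"facial": 0.4945, "body": 0.0824, "symbolic": 0.478,
              "narrative": 0.0275, "abstract": 0.2143},
    "happiness": {"facial": 0.478, "body": 0.1264, "symbolic": 0.4615,
                  "narrative": 0.0714, "abstract": 0.1648},
    "sadness": {"facial": 0.478, "body": 0.1374, "symbolic": 0.3077,
                "narrative": 0.1154, "abstract": 0.2198},
    "fear": {"facial": 0.4176, "body": 0.2253, "symbolic": 0.2418,
             "narrative": 0.1429, "abstract": 0.2857},
}


def _prominent_probs(emotion: str) -> dict[str, float]:
    mode, p_mode = _PROMINENT_MODES[emotion]
    mix = _COLOR_TABLE[emotion]
    rest = {c: mix[c][0] for c in EXPRESSIVE_COLORS if c != mode}
    total = sum(rest.values())
    probs = {c: (1.0 - p_mode) * v / total for c, v in rest.items()}
    probs[mode] = p_mode
    return probs


def default_profiles() -> dict[str, EmotionProfile]:
    """The four emotion profiles calibrated to the published statistics."""
    out = {}
    for emo in ("anger", "happiness", "sadness", "fear"):
        sc = _SCALAR_TABLE[emo]
        out[emo] = EmotionProfile(
            emotion=emo,
            color_mix=dict(_COLOR_TABLE[emo]),
            prominent_probs=_prominent_probs(emo),
            saturation=sc["saturation"],
            brightness=sc["brightness"],
            fill=sc["fill"],
            coverage=sc["coverage"],
            style_probs=dict(_STYLE_TABLE[emo]),
        )
    return out


# ---------------------------------------------------------------------------
# water-filling and feasibility
# ---------------------------------------------------------------------------

def _waterfill(weights: np.ndarray, lo: np.ndarray, hi: np.ndarray,
               target: float) -> np.ndarray:
    """Per-color channel levels x = clip(t, lo, hi) with sum(w x) = target.

    ``target`` is first clipped to the feasible interval
    [sum(w lo), sum(w hi)]; the common level t is found by bisection
    (sum(w clip(t, lo, hi)) is monotone in t).
    """
    w = weights / weights.sum()
    t_lo = float((w * lo).sum())
    t_hi = float((w * hi).sum())
    target = min(max(target, t_lo), t_hi)
    a, b = float(lo.min()), float(hi.max())
    for _ in range(60):
        mid = 0.5 * (a + b)
        if (w * np.clip(mid, lo, hi)).sum() < target:
            a = mid
        else:
            b = mid
    return np.clip(0.5 * (a + b), lo, hi)


def _sv_feasible_pct(weights: np.ndarray) -> tuple[float, float, float, float]:
    """Feasible (sat_lo, sat_hi, bright_lo, bright_hi) in % for a color mix."""
    bounds = np.array([_SV_BOUNDS[c] for c in EXPRESSIVE_COLORS], dtype=float)
    w = weights / weights.sum()
    s_lo = (w * bounds[:, 0]).sum() / 255.0 * 100.0
    s_hi = (w * bounds[:, 1]).sum() / 255.0 * 100.0
    v_lo = (w * bounds[:, 2]).sum() / 255.0 * 100.0
    v_hi = (w * bounds[:, 3]).sum() / 255.0 * 100.0
    return s_lo, s_hi, v_lo, v_hi


# ---------------------------------------------------------------------------
# vectorised composition sampling (shared by calibration and cohorts)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Params:
    """Calibrated location parameters of the generating distributions."""

    alpha: tuple[float, ...]       # prominent-share locations, one per color
    sat_mu: float
    bright_mu: float
    fill_mu: float
    cov_mu: float


def _draw_shares(alpha: np.ndarray, means: np.ndarray, sds: np.ndarray,
                 pp: np.ndarray, n: int, rng: np.random.Generator
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Mixture draw of n compositions; returns (n x 7 shares, prominent idx).

    The prominent color's share is a truncated normal at (alpha, sd);
    the remainder is split over the other colors proportionally to
    normals at the published moments clipped at zero, capped strictly
    below the prominent share so the drawn color holds the argmax.
    """
    k = len(means)
    if sds.max() == 0:
        shares = np.tile(100.0 * means / means.sum(), (n, 1))
        return shares, shares.argmax(axis=1)
    prom = rng.choice(k, size=n, p=pp)
    rows = np.arange(n)
    mu_s, sd_s = alpha[prom], sds[prom]
    s = mu_s + sd_s * rng.standard_normal(n)
    for _ in range(50):
        bad = (s < 0.0) | (s > 100.0)
        if not bad.any():
            break
        nb = int(bad.sum())
        s[bad] = mu_s[bad] + sd_s[bad] * rng.standard_normal(nb)
    s = np.clip(s, 0.5, 100.0)

    r = np.clip(means + sds * rng.standard_normal((n, k)), 0.0, None)
    r[rows, prom] = 0.0
    tot = r.sum(axis=1)
    empty = tot <= 0
    if empty.any():
        r[empty] = 1.0
        r[rows[empty], prom[empty]] = 0.0
        tot = r.sum(axis=1)
    shares = (100.0 - s)[:, None] * r / tot[:, None]

    # cap background shares strictly below the prominent share,
    # redistributing the excess; final hard clip keeps the guarantee
    cap = s * 0.99
    for _ in range(4):
        over = shares > cap[:, None]
        if not over.any():
            break
        excess = np.where(over, shares - cap[:, None], 0.0).sum(axis=1)
        shares = np.minimum(shares, cap[:, None])
        under = (~over) & (shares > 0)
        wsum = np.where(under, shares, 0.0).sum(axis=1)
        ok = wsum > 0
        scale = np.where(ok, 1.0 + excess / np.where(ok, wsum, 1.0), 1.0)
        shares = np.where(under, shares * scale[:, None], shares)
        s = np.where(ok, s, s + excess)
        cap = s * 0.99
    shares = np.minimum(shares, cap[:, None])
    shares[rows, prom] = s
    shares *= 100.0 / shares.sum(axis=1, keepdims=True)
    return shares, prom


def _sample_batch(params: _Params, profile: EmotionProfile, n: int,
                  rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Draw n compositions; returns raw and feasibility-projected values."""
    alpha = np.asarray(params.alpha)
    means = np.array([profile.color_mix[c][0] for c in EXPRESSIVE_COLORS])
    mix_sd = np.array([profile.color_mix[c][1] for c in EXPRESSIVE_COLORS])
    pp = np.array([profile.prominent_probs.get(c, 0.0) for c in EXPRESSIVE_COLORS])
    pp = pp / pp.sum()
    shares, prominent = _draw_shares(alpha, means, mix_sd, pp, n, rng)

    def trunc(mu: float, sd: float) -> np.ndarray:
        if sd == 0:
            return np.full(n, min(max(mu, 0.0), 100.0))
        out = mu + sd * rng.standard_normal(n)
        for _ in range(100):
            bad = (out < 0.0) | (out > 100.0)
            if not bad.any():
                break
            out[bad] = mu + sd * rng.standard_normal(int(bad.sum()))
        return np.clip(out, 0.0, 100.0)

    sat = trunc(params.sat_mu, profile.saturation[1])
    bright = trunc(params.bright_mu, profile.brightness[1])
    fill = trunc(params.fill_mu, profile.fill[1])
    cov = trunc(params.cov_mu, profile.coverage[1])
    # enforce coverage >= fill by joint resampling, then swap fallback
    for _ in range(50):
        bad = cov < fill
        if not bad.any():
            break
        nb = int(bad.sum())
        if profile.fill[1] > 0:
            fill[bad] = np.clip(
                params.fill_mu + profile.fill[1] * rng.standard_normal(nb), 0, 100
            )
        if profile.coverage[1] > 0:
            cov[bad] = np.clip(
                params.cov_mu + profile.coverage[1] * rng.standard_normal(nb), 0, 100
            )
        if profile.fill[1] == 0 and profile.coverage[1] == 0:
            break
    bad = cov < fill
    if bad.any():
        fill[bad], cov[bad] = cov[bad].copy(), fill[bad].copy()

    # feasibility projection the renderer will apply to saturation/brightness
    bounds = np.array([_SV_BOUNDS[c] for c in EXPRESSIVE_COLORS], dtype=float)
    w = shares / 100.0
    s_lo = w @ bounds[:, 0] / 255.0 * 100.0
    s_hi = w @ bounds[:, 1] / 255.0 * 100.0
    v_lo = w @ bounds[:, 2] / 255.0 * 100.0
    v_hi = w @ bounds[:, 3] / 255.0 * 100.0
    return {
        "shares": shares,
        "prominent": prominent,
        "sat": sat,
        "bright": bright,
        "fill": fill,
        "cov": cov,
        "sat_achieved": np.clip(sat, s_lo, s_hi),
        "bright_achieved": np.clip(bright, v_lo, v_hi),
    }


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

_calibration_cache: dict[tuple, _Params] = {}


def _clipped_normal_mean(m: float, s: float) -> float:
    """Mean of max(N(m, s), 0)."""
    if s == 0:
        return max(m, 0.0)
    from scipy import stats

    return float(m * stats.norm.cdf(m / s) + s * stats.norm.pdf(m / s))


def _trunc_mean(a: float, s: float) -> float:
    """Mean of N(a, s) truncated to [0.5, 100]."""
    if s == 0:
        return min(max(a, 0.5), 100.0)
    from scipy import stats

    lo, hi = (0.5 - a) / s, (100.0 - a) / s
    z = stats.norm.cdf(hi) - stats.norm.cdf(lo)
    if z < 1e-12:
        return 0.5 if a < 0 else 100.0
    return float(a + s * (stats.norm.pdf(lo) - stats.norm.pdf(hi)) / z)


def _alpha_for(target: float, s: float) -> float:
    """Location whose [0.5, 100]-truncated normal mean equals ``target``."""
    if s == 0:
        return target
    from scipy import optimize

    target = min(max(target, 0.6), 99.9)
    return float(optimize.brentq(lambda a: _trunc_mean(a, s) - target, -600.0, 700.0))


def _solve_prominent_means(t_eff: np.ndarray, means: np.ndarray,
                           sds: np.ndarray, pp: np.ndarray) -> np.ndarray:
    """Conditional prominent-share means solving the mean-consistency system.

    Ignoring the cap, E[share_c] = p_c S_c + sum_{d!=c} p_d (100 - S_d) w_cd
    with background weights w_cd from the clipped-normal means; linear in
    the S vector (rank-deficient by the sum-to-100 identity, solved by
    least squares). The Monte-Carlo correction loop absorbs what the
    approximation misses.
    """
    k = len(means)
    mt = np.array([_clipped_normal_mean(m, s) for m, s in zip(means, sds)])
    M = mt.sum()
    W = np.zeros((k, k))
    for d in range(k):
        denom = M - mt[d]
        if denom > 0:
            for c in range(k):
                if c != d:
                    W[c, d] = mt[c] / denom
    A = np.zeros((k, k))
    for c in range(k):
        A[c, c] = pp[c]
        for d in range(k):
            if d != c:
                A[c, d] = -pp[d] * W[c, d]
    rhs = t_eff - (W * pp[None, :] * 100.0).sum(axis=1)
    S, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    return np.clip(S, 1.0, 99.9)


def calibrated_params(profile: EmotionProfile) -> _Params:
    """Location parameters making achieved population means equal the profile.

    The prominent-share locations come from the analytic mean-consistency
    system; a damped correction loop on a fixed internal random stream
    (common random numbers, so the iteration is a deterministic smooth
    map) removes the residual bias from capping, clipping and the
    saturation/brightness feasibility projection. Cached per profile.
    """
    key = profile._key()
    if key in _calibration_cache:
        return _calibration_cache[key]

    targets = np.array([profile.color_mix[c][0] for c in EXPRESSIVE_COLORS])
    sds = np.array([profile.color_mix[c][1] for c in EXPRESSIVE_COLORS])
    pp = np.array([profile.prominent_probs.get(c, 0.0) for c in EXPRESSIVE_COLORS])
    pp = pp / pp.sum()
    degenerate_shares = sds.max() == 0

    t_eff = targets.copy()
    params = _Params(
        alpha=tuple(targets),
        sat_mu=profile.saturation[0],
        bright_mu=profile.brightness[0],
        fill_mu=profile.fill[0],
        cov_mu=profile.coverage[0],
    )
    for _ in range(_CAL_ITER):
        if not degenerate_shares:
            S = _solve_prominent_means(t_eff, targets, sds, pp)
            alpha = tuple(_alpha_for(S[c], sds[c]) for c in range(len(S)))
            params = replace(params, alpha=alpha)
        rng = np.random.default_rng(_CAL_SEED)   # common random numbers
        batch = _sample_batch(params, profile, _CAL_BATCH, rng)
        err_mix = targets - batch["shares"].mean(axis=0)
        err_sat = profile.saturation[0] - batch["sat_achieved"].mean()
        err_bright = profile.brightness[0] - batch["bright_achieved"].mean()
        err_fill = profile.fill[0] - batch["fill"].mean()
        err_cov = profile.coverage[0] - batch["cov"].mean()
        if max(np.abs(err_mix).max(), abs(err_sat), abs(err_bright),
               abs(err_fill), abs(err_cov)) < 0.02:
            break
        t_eff = t_eff + _CAL_DAMPING * err_mix
        params = replace(
            params,
            sat_mu=float(np.clip(params.sat_mu + _CAL_DAMPING * err_sat, -200, 300)),
            bright_mu=float(np.clip(params.bright_mu + _CAL_DAMPING * err_bright, -200, 300)),
            fill_mu=float(np.clip(params.fill_mu + _CAL_DAMPING * err_fill, -200, 300)),
            cov_mu=float(np.clip(params.cov_mu + _CAL_DAMPING * err_cov, -200, 300)),
        )
    _calibration_cache[key] = params
    return params


# ---------------------------------------------------------------------------
# public sampling API
# ---------------------------------------------------------------------------

def sample_composition(
    profile: EmotionProfile,
    rng: np.random.Generator,
    source_id: str = "",
) -> GroundTruth:
    """Draw one ground-truth composition from a calibrated profile."""
    params = calibrated_params(profile)
    batch = _sample_batch(params, profile, 1, rng)
    shares = {c: float(batch["shares"][0, i]) for i, c in enumerate(EXPRESSIVE_COLORS)}
    styles = {
        cat: int(rng.random() < profile.style_probs.get(cat, 0.0))
        for cat in STYLE_CATEGORIES
    }
    return GroundTruth(
        source_id=source_id or profile.emotion,
        emotion=profile.emotion,
        shares=shares,
        prominent=EXPRESSIVE_COLORS[int(batch["prominent"][0])],
        saturation=float(batch["sat"][0]),
        brightness=float(batch["bright"][0]),
        fill=float(batch["fill"][0]),
        coverage=float(batch["cov"][0]),
        styles=styles,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _largest_remainder(shares: np.ndarray, total: int) -> np.ndarray:
    """Integer counts summing to ``total`` proportional to ``shares``."""
    quota = shares / shares.sum() * total
    counts = np.floor(quota).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def _pick_sv(color: str, s0: int, v0: int, palette: ColorPalette
             ) -> tuple[np.ndarray, int, int]:
    """RGB triple for ``color`` near (s0, v0) that survives the round trip.

    Searches a small neighbourhood until the forward conversion of the
    painted RGB classifies back to ``color``; returns the RGB triple and
    the realised (S, V) after the round trip, used for exact bookkeeping.
    """
    from .color_features import classify_pixel

    h = _HUES[color]
    s_lo, s_hi, v_lo, v_hi = _SV_BOUNDS[color]
    deltas = (0, 1, -1, 2, -2, 3, -3)
    for dv in deltas:
        v = v0 + dv
        if not (v_lo <= v <= v_hi):
            continue
        for ds in deltas:
            s = s0 + ds
            if not (s_lo <= s <= s_hi):
                continue
            rgb = hsv_to_rgb_opencv(np.array([h, s, v], dtype=float))
            back = rgb_to_hsv_opencv(rgb.reshape(1, 1, 3))[0, 0]
            if classify_pixel(tuple(int(x) for x in back), palette) == color:
                return rgb, int(back[1]), int(back[2])
    # last resort: box centre (always classifiable by construction)
    s = (s_lo + s_hi) // 2
    v = (v_lo + v_hi) // 2
    rgb = hsv_to_rgb_opencv(np.array([h, s, v], dtype=float))
    back = rgb_to_hsv_opencv(rgb.reshape(1, 1, 3))[0, 0]
    return rgb, int(back[1]), int(back[2])


def render_drawing(
    gt: GroundTruth,
    canvas: tuple[int, int] = (256, 256),
    palette: ColorPalette | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[RasterImage, GroundTruth]:
    """Paint a drawing realising ``gt``; returns (image, achieved ground truth).

    Count-based metrics (shares, fill, coverage) are realised exactly up
    to pixel rounding; saturation/brightness are realised up to the
    feasible set implied by the color mix and integer rounding (within
    about two points). The achieved ground truth records the pixel-exact
    values.
    """
    palette = palette or ColorPalette()
    rng = rng or np.random.default_rng()
    w, h = canvas
    if w < 64 or h < 64:
        raise ValueError("canvas must be at least 64x64")
    total = w * h
    cov_n = int(np.clip(round(gt.coverage / 100.0 * total), 1, total))
    fill_n = int(np.clip(round(gt.fill / 100.0 * total), 1, cov_n))

    # star-shaped blob of exactly cov_n pixels
    cy = h / 2.0 + rng.uniform(-0.08, 0.08) * h
    cx = w / 2.0 + rng.uniform(-0.08, 0.08) * w
    yy, xx = np.indices((h, w), dtype=float)
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    dist = np.hypot(dy, dx)
    rfun = np.ones_like(theta)
    for k in range(2, 6):
        rfun += rng.uniform(0.0, 0.12) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    rfun = np.clip(rfun, 0.3, None)
    ratio = (dist / rfun).ravel()
    region_idx = np.argpartition(ratio, cov_n - 1)[:cov_n]
    region = np.zeros(total, dtype=bool)
    region[region_idx] = True

    # carve an interior hole (never touching the blob or canvas boundary)
    hole_n = cov_n - fill_n
    drawn = region.copy()
    if hole_n > 0:
        interior = ndimage.binary_erosion(
            region.reshape(h, w),
            structure=ndimage.generate_binary_structure(2, 1),
            border_value=0,
        ).ravel()
        cand = region_idx[np.argsort(ratio[region_idx], kind="stable")]
        cand = cand[interior[cand]]
        hole = cand[: min(hole_n, len(cand))]
        drawn[hole] = False
    drawn_idx = np.flatnonzero(drawn)
    n_drawn = len(drawn_idx)

    shares = np.array([gt.shares[c] for c in EXPRESSIVE_COLORS])
    counts = _largest_remainder(shares, n_drawn)

    # water-fill S and V over the colors actually painted
    active = counts > 0
    bounds = np.array([_SV_BOUNDS[c] for c in EXPRESSIVE_COLORS], dtype=float)
    wts = counts[active].astype(float)
    s_levels = _waterfill(wts, bounds[active, 0], bounds[active, 1],
                          gt.saturation / 100.0 * 255.0)
    v_levels = _waterfill(wts, bounds[active, 2], bounds[active, 3],
                          gt.brightness / 100.0 * 255.0)

    # paint contiguous angular wedges per color
    order = drawn_idx[np.argsort(theta.ravel()[drawn_idx], kind="stable")]
    img = np.full((total, 3), 255, dtype=np.uint8)
    pos = 0
    realized_s = np.zeros(len(EXPRESSIVE_COLORS))
    realized_v = np.zeros(len(EXPRESSIVE_COLORS))
    lvl = 0
    for i, c in enumerate(EXPRESSIVE_COLORS):
        if counts[i] == 0:
            continue
        s0 = int(round(s_levels[lvl]))
        v0 = int(round(v_levels[lvl]))
        lvl += 1
        rgb, s_real, v_real = _pick_sv(c, s0, v0, palette)
        realized_s[i], realized_v[i] = s_real, v_real
        img[order[pos:pos + counts[i]]] = rgb
        pos += counts[i]

    image = RasterImage(img.reshape(h, w, 3), gt.source_id)
    achieved = GroundTruth(
        source_id=gt.source_id,
        emotion=gt.emotion,
        shares={c: 100.0 * counts[i] / n_drawn for i, c in enumerate(EXPRESSIVE_COLORS)},
        prominent=EXPRESSIVE_COLORS[int(np.argmax(counts))],
        saturation=float((counts * realized_s).sum() / n_drawn / 255.0 * 100.0),
        brightness=float((counts * realized_v).sum() / n_drawn / 255.0 * 100.0),
        fill=100.0 * n_drawn / total,
        coverage=100.0 * cov_n / total,
        styles=dict(gt.styles),
    )
    return image, achieved


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """A generated synthetic cohort: images plus ground-truth tables."""

    images: list[RasterImage]
    intended: list[GroundTruth]
    achieved: list[GroundTruth]
    seed: int

    @property
    def ground_truth(self) -> pd.DataFrame:
        return pd.DataFrame([g.as_row() for g in self.achieved]).set_index("source_id")

    @property
    def styles(self) -> pd.DataFrame:
        rows = [
            {"source_id": g.source_id, **{c: g.styles[c] for c in STYLE_CATEGORIES}}
            for g in self.achieved
        ]
        return pd.DataFrame(rows).set_index("source_id")

    @property
    def emotions(self) -> pd.Series:
        return pd.Series(
            {g.source_id: g.emotion for g in self.achieved}, name="emotion"
        )


def generate_cohort(
    profiles: Mapping[str, EmotionProfile] | None = None,
    n_per_emotion: int = 182,
    seed: int = 0,
    *,
    canvas: tuple[int, int] = (256, 256),
    out_dir: str | Path | None = None,
    palette: ColorPalette | None = None,
) -> Cohort:
    """Generate ``n_per_emotion`` drawings for each emotion profile.

    Fully reproducible from ``seed``: one sequential random stream
    drives sampling and rendering. When ``out_dir`` is given, writes
    ``{participant}_{emotion}.png`` files, ``ground_truth.csv``,
    ``styles.csv`` and a ``manifest.json`` recording seed, canvas and
    palette hash.
    """
    if n_per_emotion < 1:
        raise ValueError("n_per_emotion must be >= 1")
    profiles = profiles or default_profiles()
    palette = palette or ColorPalette()
    rng = np.random.default_rng(seed)
    images: list[RasterImage] = []
    intended: list[GroundTruth] = []
    achieved: list[GroundTruth] = []
    for i in range(n_per_emotion):
        for emo, profile in profiles.items():
            sid = f"p{i + 1:03d}_{emo}"
            gt = sample_composition(profile, rng, source_id=sid)
            img, ach = render_drawing(gt, canvas=canvas, palette=palette, rng=rng)
            images.append(img)
            intended.append(gt)
            achieved.append(ach)
    cohort = Cohort(images=images, intended=intended, achieved=achieved, seed=seed)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for img in images:
            save_image(img, out / f"{img.source_id}.png")
        cohort.ground_truth.to_csv(out / "ground_truth.csv")
        cohort.styles.to_csv(out / "styles.csv")
        manifest = {
            "seed": seed,
            "n_per_emotion": n_per_emotion,
            "canvas": list(canvas),
            "palette_hash": palette.content_hash(),
            "emotions": list(profiles.keys()),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return cohort
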
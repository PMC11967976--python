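"""Segmentation and the three feature families: DWT, EMD, SLBP.

Each channel is divided into fixed-length non-overlapping windows
(2048 samples = 16 s at 128 Hz by default); a feature vector is computed
per window:

* **DWT** — three-level db4 wavelet decomposition; the four statistical
  features (Shannon entropy, mean, variance, energy) of each of D1, D2,
  D3, A3 give 16 features per channel.
* **EMD** — empirical mode decomposition into 3 intrinsic mode functions
  by cubic-spline envelope sifting; the same four statistics per IMF give
  12 features per channel.
* **SLBP** — symmetrically-weighted local binary pattern: at every
  interior sample the signs of the differences to the L left and L right
  neighbours are thresholded and combined with mirrored binary weights
  into an integer code in [0, 2*(2^L - 1)]; the code histogram over the
  window is the feature vector (31 bins for the default L = 4).

The SLBP weighting is symmetric on purpose: the left neighbourhood uses
weights 2^(L-1-m) (m = 0..L-1, oldest sample heaviest) and the right uses
2^m, so a pattern and its time-reversal swap the two partial sums instead
of mapping to unrelated codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt

from endeeg.channel_rank import EntropyConfig, shannon_entropy
from endeeg.errors import ValidationError

STAT_NAMES = ("entropy", "mean", "variance", "energy")


@dataclass
class SegmentationConfig:
    window_samples: int = 2048  # 16 s at 128 Hz
    overlap: int = 0  # fixed: windows are disjoint

    def __post_init__(self) -> None:
        if self.window_samples < 2:
            raise ValidationError("window_samples must be >= 2")
        if self.overlap != 0:
            raise ValidationError("only non-overlapping segmentation is supported")


@dataclass
class Segment:
    """One fixed-length window of one channel, with provenance."""

    values: np.ndarray
    subject_id: str = ""
    channel: str = ""
    label: str = ""
    index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("segment contains non-finite samples")


@dataclass
class DWTConfig:
    wavelet: str = "db4"
    levels: int = 3
    boundary_mode: str = "periodization"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValidationError("levels must be >= 1")
        if self.boundary_mode not in ("periodization", "symmetric"):
            raise ValidationError("boundary_mode must be 'periodization' or 'symmetric'")


@dataclass
class EMDConfig:
    n_imfs: int = 3
    max_siftings: int = 100
    sift_tolerance: float = 0.2

    def __post_init__(self) -> None:
        if self.n_imfs < 1:
            raise ValidationError("n_imfs must be >= 1")
        if self.max_siftings < 1 or self.sift_tolerance <= 0:
            raise ValidationError("max_siftings and sift_tolerance must be positive")


@dataclass
class SLBPConfig:
    """Neighbourhood half-width L; code alphabet size is 2*(2^L - 1) + 1."""

    L: int = 4

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValidationError("L must be >= 1")

    @property
    def n_codes(self) -> int:
        return 2 * (2**self.L - 1) + 1


def segment_channel(
    x: np.ndarray,
    cfg: SegmentationConfig | None = None,
    subject_id: str = "",
    channel: str = "",
    label: str = "",
) -> list[Segment]:
    """Consecutive non-overlapping windows; a trailing remainder shorter
    than the window is discarded. Indices are 0-based in time order."""
    cfg = cfg or SegmentationConfig()
    x = np.asarray(x, dtype=float).ravel()
    w = cfg.window_samples
    n_seg = len(x) // w
    return [
        Segment(x[i * w : (i + 1) * w], subject_id=subject_id, channel=channel,
                label=label, index=i)
        for i in range(n_seg)
    ]


def stat_features(v: np.ndarray, entropy_cfg: EntropyConfig | None = None) -> tuple[float, float, float, float]:
    """(Shannon entropy, mean, population variance, energy) of a vector.

    Entropy reuses the channel-ranking histogram machinery, binned over
    the vector's own min-max; energy is the plain sum of squares.
    """
    v = np.asarray(v, dtype=float).ravel()
    if v.size == 0:
        raise ValidationError("cannot compute statistics of an empty vector")
    ent = shannon_entropy(v, entropy_cfg)
    return ent, float(v.mean()), float(v.var()), float(np.sum(v * v))


def _stat_series(prefix: str, vectors: list[tuple[str, np.ndarray]],
                 entropy_cfg: EntropyConfig | None) -> pd.Series:
    names, values = [], []
    for sub, vec in vectors:
        stats = stat_features(vec, entropy_cfg)
        for stat_name, val in zip(STAT_NAMES, stats):
            names.append(f"{sub}_{stat_name}")
            values.append(val)
    return pd.Series(values, index=names, name=prefix)


def dwt_features(
    seg: Segment,
    cfg: DWTConfig | None = None,
    entropy_cfg: EntropyConfig | None = None,
) -> pd.Series:
    """16 features: (D1, D2, D3, A3) x (entropy, mean, variance, energy)."""
    cfg = cfg or DWTConfig()
    x = seg.values
    max_level = pywt.dwt_max_level(len(x), cfg.wavelet)
    if cfg.levels > max_level or 2**cfg.levels > len(x):
        raise ValidationError(
            f"segment of {len(x)} samples too short for {cfg.levels}-level {cfg.wavelet}"
        )
    coeffs = pywt.wavedec(x, cfg.wavelet, mode=cfg.boundary_mode, level=cfg.levels)
    approx, details = coeffs[0], coeffs[1:]  # details: [D_levels, ..., D1]
    subbands = [(f"D{i}", details[-i]) for i in range(1, cfg.levels + 1)]
    subbands.append((f"A{cfg.levels}", approx))
    return _stat_series("dwt", subbands, entropy_cfg)


# ---------------------------------------------------------------- EMD ----

def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateau-tolerant)."""
    d = np.diff(x)
    sign = np.sign(d)
    # carry the previous non-zero slope across flat runs
    nz = sign != 0
    if not nz.any():
        return np.array([], dtype=int), np.array([], dtype=int)
    idx = np.where(nz, np.arange(len(sign)), -1)
    np.maximum.accumulate(idx, out=idx)
    filled = np.where(idx >= 0, sign[np.clip(idx, 0, None)], 0)
    change = np.diff(filled)
    maxima = np.where(change < 0)[0] + 1
    minima = np.where(change > 0)[0] + 1
    return maxima, minima


def _envelope(t_ext: np.ndarray, v_ext: np.ndarray, n: int) -> np.ndarray:
    """Cubic-spline envelope through extrema, mirrored beyond both ends."""
    from scipy.interpolate import CubicSpline

    k = min(2, len(t_ext))
    left_t = -t_ext[:k][::-1]
    left_v = v_ext[:k][::-1]
    right_t = 2 * (n - 1) - t_ext[-k:][::-1]
    right_v = v_ext[-k:][::-1]
    t = np.concatenate([left_t, t_ext, right_t]).astype(float)
    v = np.concatenate([left_v, v_ext, right_v])
    t, keep = np.unique(t, return_index=True)
    return CubicSpline(t, v[keep])(np.arange(n))


@dataclass
class EMDResult:
    """Exactly ``n_imfs`` IMF vectors plus the residue; ``degenerate`` is
    set when sifting stopped early (remaining IMFs are zero vectors)."""

    imfs: list[np.ndarray]
    residue: np.ndarray
    degenerate: bool = False


def emd_sift(seg: Segment, cfg: EMDConfig | None = None) -> EMDResult:
    """Empirical mode decomposition by envelope-mean sifting.

    Each candidate IMF is refined until the Cauchy criterion
    ``sum((h_prev - h)^2) / sum(h_prev^2) < sift_tolerance`` or
    ``max_siftings`` iterations. Sifting of further IMFs stops when the
    running residue has fewer than two maxima or two minima (monotonic /
    constant); the signal always equals the IMF sum plus the residue to
    floating-point precision by construction.
    """
    cfg = cfg or EMDConfig()
    x = seg.values.astype(float)
    imfs: list[np.ndarray] = []
    residue = x.copy()
    degenerate = False
    n = len(x)
    for _ in range(cfg.n_imfs):
        maxima, minima = _local_extrema(residue)
        if len(maxima) < 2 or len(minima) < 2:
            degenerate = True
            imfs.append(np.zeros(n))
            continue
        h = residue.copy()
        for _ in range(cfg.max_siftings):
            maxima, minima = _local_extrema(h)
            if len(maxima) < 2 or len(minima) < 2:
                break
            upper = _envelope(maxima, h[maxima], n)
            lower = _envelope(minima, h[minima], n)
            mean_env = 0.5 * (upper + lower)
            h_new = h - mean_env
            denom = float(np.sum(h * h)) + 1e-300
            sd = float(np.sum((h - h_new) ** 2)) / denom
            h = h_new
            if sd < cfg.sift_tolerance:
                break
        imfs.append(h)
        residue = residue - h
    # recompute so additivity is exact to float rounding
    residue = x - np.sum(imfs, axis=0)
    return EMDResult(imfs=imfs, residue=residue, degenerate=degenerate)


def emd_features(
    seg: Segment,
    cfg: EMDConfig | None = None,
    entropy_cfg: EntropyConfig | None = None,
) -> pd.Series:
    """12 features: (IMF1..IMF3) x (entropy, mean, variance, energy)."""
    cfg = cfg or EMDConfig()
    result = emd_sift(seg, cfg)
    vectors = [(f"imf{i + 1}", imf) for i, imf in enumerate(result.imfs)]
    return _stat_series("emd", vectors, entropy_cfg)


# --------------------------------------------------------------- SLBP ----

def slbp_code(x: np.ndarray, n: int, cfg: SLBPConfig | None = None) -> int:
    """SLBP code of sample ``n``: thresholded neighbourhood differences
    with mirrored weights.

    LHS = sum_m f(x[n+m-L] - x[n]) * 2^(L-1-m), RHS = sum_m
    f(x[n+m+1] - x[n]) * 2^m, with f(d) = 1 for d >= 0 else 0; the code
    is LHS + RHS. Requires full neighbourhoods (L <= n <= len(x)-L-1).
    """
    cfg = cfg or SLBPConfig()
    x = np.asarray(x, dtype=float).ravel()
    L = cfg.L
    if not L <= n <= len(x) - L - 1:
        raise ValidationError(f"index {n} lacks a full +-{L} neighbourhood in length {len(x)}")
    lhs = sum(int(x[n + m - L] - x[n] >= 0) * 2 ** (L - 1 - m) for m in range(L))
    rhs = sum(int(x[n + m + 1] - x[n] >= 0) * 2**m for m in range(L))
    return lhs + rhs


def _slbp_codes(x: np.ndarray, L: int) -> np.ndarray:
    """Vectorized SLBP codes for every interior index n in [L, len(x)-L-1]."""
    n = len(x)
    center = x[L : n - L]
    codes = np.zeros(n - 2 * L, dtype=int)
    for m in range(L):
        codes += (x[m : n - 2 * L + m] - center >= 0) * 2 ** (L - 1 - m)
        codes += (x[L + m + 1 : n - L + m + 1] - center >= 0) * 2**m
    return codes


def slbp_features(seg: Segment, cfg: SLBPConfig | None = None) -> pd.Series:
    """Raw-count histogram of SLBP codes over all interior samples.

    With L = 4 the 31 possible codes 0..30 give 31 features whose counts
    sum to W - 2L. No edge padding: codes are computed only where both
    neighbourhoods are complete.
    """
    cfg = cfg or SLBPConfig()
    x = seg.values
    if len(x) < 2 * cfg.L + 1:
        raise ValidationError(f"segment of {len(x)} samples shorter than 2L+1 = {2 * cfg.L + 1}")
    codes = _slbp_codes(x, cfg.L)
    counts = np.bincount(codes, minlength=cfg.n_codes)
    names = [f"slbp_c{c:02d}" for c in range(cfg.n_codes)]
    return pd.Series(counts.astype(float), index=names, name="slbp")


# ------------------------------------------------- cohort-level table ----

EXTRACTORS = ("dwt", "emd", "slbp")


def extract_segment_features(seg: Segment, extractor: str, *,
                             dwt_cfg: DWTConfig | None = None,
                             emd_cfg: EMDConfig | None = None,
                             slbp_cfg: SLBPConfig | None = None,
                             entropy_cfg: EntropyConfig | None = None) -> pd.Series:
    if extractor == "dwt":
        return dwt_features(seg, dwt_cfg, entropy_cfg)
    if extractor == "emd":
        return emd_features(seg, emd_cfg, entropy_cfg)
    if extractor == "slbp":
        return slbp_features(seg, slbp_cfg)
    raise ValidationError(f"extractor must be one of {EXTRACTORS}")


def channel_feature_table(
    recordings: list,
    channel: str,
    extractor: str,
    seg_cfg: SegmentationConfig | None = None,
    **extractor_cfgs,
) -> pd.DataFrame:
    """Features of every window of one channel across a cohort.

    Rows carry (subject_id, label, segment_index) provenance followed by
    the extractor's named features.
    """
    seg_cfg = seg_cfg or SegmentationConfig()
    rows = []
    for rec in recordings:
        for seg in segment_channel(rec.channel(channel), seg_cfg,
                                   subject_id=rec.subject_id, channel=channel,
                                   label=rec.label):
            feats = extract_segment_features(seg, extractor, **extractor_cfgs)
            row = {"subject_id": seg.subject_id, "label": seg.label,
                   "segment_index": seg.index}
            row.update(feats.to_dict())
            rows.append(row)
    return pd.DataFrame(rows)
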
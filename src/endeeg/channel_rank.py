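"""Entropy-difference (EnD) channel scoring and ranking.

A channel's Shannon entropy is computed from the histogram of its sample
values: the samples are binned into ``n_bins`` uniform-width bins, the bin
frequencies normalized to a probability mass function p, and

    H = - sum_i p_i * log2(p_i)        (0 * log2 0 := 0),

in bits. For a two-class training set the EnD statistic of channel C is

    EnD(C) = | H_A(C) - H_B(C) |,

where H_A is the entropy of the channel pooled over all class-A training
subjects and H_B likewise for class B. A large EnD marks a channel whose
amplitude distribution changes with the condition; channels are ranked by
descending EnD and the top N retained. The classical entropy-only ranking
(descending entropy of the pooled two-class training samples) is provided
as the baseline.

Binning policy matters. With ``pooled-min-max`` (the default) the two
class histograms of a channel share bin edges spanning both classes'
training samples, so the two entropies are measured on a common amplitude
grid and a pure scale (variance) difference between classes is visible.
With ``per-signal-min-max`` each signal is binned over its own range,
which makes the entropy invariant to amplitude scaling — useful as a
normalization-free variant, but blind to variance effects by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from endeeg.eeg_io import Recording
from endeeg.errors import ValidationError

RANGE_POLICIES = ("pooled-min-max", "per-signal-min-max")


@dataclass
class EntropyConfig:
    """Discretization used to form the probability mass function.

    256 uniform-width bins approximate an 8-bit amplitude quantization, a
    common EEG convention, and bound entropies in [0, 8] bits. The log
    base is fixed at 2 (entropies in bits).
    """

    n_bins: int = 256
    range_policy: str = "pooled-min-max"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValidationError("n_bins must be >= 2")
        if self.range_policy not in RANGE_POLICIES:
            raise ValidationError(f"range_policy must be one of {RANGE_POLICIES}")


def shannon_entropy(
    x: np.ndarray,
    cfg: EntropyConfig | None = None,
    bin_range: tuple[float, float] | None = None,
) -> float:
    """Histogram Shannon entropy of a sample vector, in bits.

    ``bin_range`` fixes the bin edges externally (used to share edges
    between class pools); by default the vector's own min-max is used.
    A degenerate range (constant signal) has a single occupied bin and
    entropy exactly 0. Result lies in [0, log2(n_bins)].
    """
    cfg = cfg or EntropyConfig()
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValidationError("cannot compute entropy of an empty vector")
    if not np.all(np.isfinite(x)):
        raise ValidationError("entropy input contains non-finite samples")
    if bin_range is None:
        lo, hi = float(x.min()), float(x.max())
    else:
        lo, hi = float(bin_range[0]), float(bin_range[1])
    if not lo < hi:
        return 0.0
    counts, _ = np.histogram(x, bins=cfg.n_bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log2(p)))


def entropy_difference(h_a: float, h_b: float) -> float:
    """EnD statistic: absolute difference of two channel entropies (bits)."""
    if h_a < 0 or h_b < 0:
        raise ValidationError("entropies must be non-negative")
    return abs(h_a - h_b)


def class_channel_entropies(
    train: list[Recording],
    cfg: EntropyConfig | None = None,
    class_a: str = "adhd",
    class_b: str = "control",
) -> pd.DataFrame:
    """Per-channel class entropies, EnD, and the pooled-entropy baseline.

    For each channel (matched across recordings by normalized name, not
    position) the samples of all class-A training subjects are
    concatenated and measured with one entropy evaluation, likewise for
    class B; under the pooled-min-max policy both evaluations share bin
    edges spanning the union of the two pools. ``H_pooled`` is the
    entropy of the two-class concatenation over its own range (the
    class-agnostic baseline ranking criterion).

    Returns a DataFrame with columns channel, H_classA, H_classB, EnD,
    H_pooled, in the montage order of the first training recording.
    """
    cfg = cfg or EntropyConfig()
    if not train:
        raise ValidationError("empty training set")
    labels = {rec.label for rec in train}
    for cls in (class_a, class_b):
        if cls not in labels:
            raise ValidationError(f"training set has no recordings of class {cls!r}")
    montage = list(train[0].channel_names)
    for rec in train[1:]:
        if set(rec.channel_names) != set(montage):
            raise ValidationError(
                f"montage mismatch: {rec.subject_id!r} has channels "
                f"{sorted(rec.channel_names)} vs {sorted(montage)}"
            )
    rows = []
    for name in montage:
        pool_a = np.concatenate([r.channel(name) for r in train if r.label == class_a])
        pool_b = np.concatenate([r.channel(name) for r in train if r.label == class_b])
        if cfg.range_policy == "pooled-min-max":
            lo = min(pool_a.min(), pool_b.min())
            hi = max(pool_a.max(), pool_b.max())
            shared = (float(lo), float(hi))
            h_a = shannon_entropy(pool_a, cfg, bin_range=shared)
            h_b = shannon_entropy(pool_b, cfg, bin_range=shared)
        else:
            h_a = shannon_entropy(pool_a, cfg)
            h_b = shannon_entropy(pool_b, cfg)
        h_pooled = shannon_entropy(np.concatenate([pool_a, pool_b]), cfg)
        rows.append(
            {
                "channel": name,
                "H_classA": h_a,
                "H_classB": h_b,
                "EnD": entropy_difference(h_a, h_b),
                "H_pooled": h_pooled,
            }
        )
    return pd.DataFrame(rows)


def rank_channels(table: pd.DataFrame, criterion: str = "end") -> pd.DataFrame:
    """Attach 1-based ``rank_end`` and ``rank_en`` columns.

    ``rank_end`` orders channels by descending EnD; ``rank_en`` by
    descending pooled-training entropy. Ties keep the input (montage)
    order — stable and reportable. ``criterion`` selects which ranking
    sorts the returned table ("end" or "en"); both columns are present
    either way.
    """
    if criterion not in ("end", "en"):
        raise ValidationError("criterion must be 'end' or 'en'")
    if len(table) == 0:
        raise ValidationError("cannot rank an empty score table")
    table = table.reset_index(drop=True).copy()
    order_end = np.argsort(-table["EnD"].to_numpy(), kind="stable")
    order_en = np.argsort(-table["H_pooled"].to_numpy(), kind="stable")
    rank_end = np.empty(len(table), dtype=int)
    rank_en = np.empty(len(table), dtype=int)
    rank_end[order_end] = np.arange(1, len(table) + 1)
    rank_en[order_en] = np.arange(1, len(table) + 1)
    table["rank_end"] = rank_end
    table["rank_en"] = rank_en
    sort_col = "rank_end" if criterion == "end" else "rank_en"
    return table.sort_values(sort_col, kind="stable").reset_index(drop=True)


def select_top(table: pd.DataFrame, n: int, criterion: str = "end") -> list[str]:
    """First ``n`` channel names by the requested ranking."""
    if criterion not in ("end", "en"):
        raise ValidationError("criterion must be 'end' or 'en'")
    col = "rank_end" if criterion == "end" else "rank_en"
    if col not in table.columns:
        raise ValidationError("table has no ranks; call rank_channels first")
    if not 1 <= n <= len(table):
        raise ValidationError(f"n must be in [1, {len(table)}], got {n}")
    return list(table.sort_values(col, kind="stable")["channel"].head(n))
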
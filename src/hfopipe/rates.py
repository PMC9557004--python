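"""Per-channel HFO rates, the HFO area, and test-retest reliability.

The spatial profile of the HFO rate — events/minute on every bipolar
channel — is the quantity that localizes epileptogenic tissue. Its stability
across NREM intervals is quantified by the normalized scalar product between
per-interval rate vectors, tested against a channel-permutation null. The
"HFO area" is the set of channels with at least one event per minute whose
rate also exceeds the 95th percentile of the patient's rate distribution.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd


def compute_rates(
    events,
    intervals: list[tuple[float, float]],
    channels: list[str],
    kind: str = "HFO",
    per_interval: bool = False,
):
    """Events/minute per bipolar channel, pooled or per interval.

    ``events`` is an iterable of objects with ``channel``, ``kind`` and
    ``interval_index`` attributes (HFOEvent) or a DataFrame with those
    columns. The pooled rate divides the per-channel count of ``kind``
    events by the total interval duration in minutes; the per-interval
    variant divides each interval's count by that interval's minutes and
    returns a DataFrame (intervals x channels).
    """
    total_min = sum(b - a for a, b in intervals) / 60.0
    if total_min <= 0:
        raise ValueError("total interval duration must be positive")
    if isinstance(events, pd.DataFrame):
        df = events
    else:
        df = pd.DataFrame(
            [{"channel": e.channel, "kind": e.kind, "interval_index": e.interval_index} for e in events],
            columns=["channel", "kind", "interval_index"],
        )
    df = df[df["kind"] == kind]
    if not per_interval:
        counts = df.groupby("channel").size()
        return counts.reindex(channels, fill_value=0).astype(float) / total_min

    out = pd.DataFrame(0.0, index=range(len(intervals)), columns=channels)
    for k, (a, b) in enumerate(intervals):
        minutes = (b - a) / 60.0
        counts = df[df["interval_index"] == k].groupby("channel").size()
        out.loc[k] = counts.reindex(channels, fill_value=0).astype(float) / minutes
    return out


def hfo_area(rates: pd.Series, percentile: float = 95.0, min_rate: float = 1.0) -> set[str]:
    """Channels with rate >= min_rate strictly exceeding the percentile threshold.

    The threshold is the linear-interpolation percentile of the patient's
    full channel-rate distribution; "exceeding" is strict, so a degenerate
    all-equal distribution yields an empty area.
    """
    if len(rates) < 2:
        raise ValueError("HFO area needs at least 2 channels")
    threshold = float(np.percentile(rates.values, percentile))
    return {ch for ch, r in rates.items() if r > threshold and r >= min_rate}


def normalized_scalar_product(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity of two rate vectors; NaN if either is all-zero."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("rate vectors must have identical channel dimension")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return float("nan")
    return float(np.dot(a, b) / (na * nb))


def permutation_significance(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 5000,
    seed: int | None = None,
    alpha_percentile: float = 97.5,
):
    """Test the scalar product of two rate vectors against a permutation null.

    The channel order of ``b`` is permuted ``n_perm`` times; the observed
    product is significant when it exceeds the ``alpha_percentile`` of the
    permuted products. Constant vectors make the null degenerate (every
    permutation gives the same product): flagged, never significant.

    Returns (true_value, null_distribution, significant).
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    true_value = normalized_scalar_product(a, b)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return true_value, np.full(n_perm, true_value), False
    rng = np.random.default_rng(seed)
    B = rng.permuted(np.tile(b, (n_perm, 1)), axis=1)
    null = (B @ a) / (np.linalg.norm(a) * np.linalg.norm(b))
    significant = bool(true_value > np.percentile(null, alpha_percentile))
    return true_value, null, significant


def test_retest_summary(
    rate_vectors: pd.DataFrame | np.ndarray,
    n_perm: int = 5000,
    seed: int | None = None,
) -> dict:
    """Reliability of the rate spatial profile over all interval pairs.

    ``rate_vectors`` is intervals x channels. Reports the mean and SD of the
    normalized scalar product over all unordered interval pairs, in percent,
    and the number of pairs significant under the permutation test.
    All-zero intervals contribute undefined (NaN) products, excluded from
    the mean with a logged count.
    """
    V = np.asarray(rate_vectors, dtype=float)
    if V.shape[0] < 2:
        raise ValueError("test-retest needs at least 2 intervals")
    products, flags = [], []
    rng = np.random.default_rng(seed)
    for i, j in combinations(range(V.shape[0]), 2):
        t, _, sig = permutation_significance(V[i], V[j], n_perm=n_perm, seed=int(rng.integers(2**31)))
        products.append(t)
        flags.append(sig)
    products = np.asarray(products)
    ok = np.isfinite(products)
    mean = float(np.mean(products[ok]) * 100) if ok.any() else float("nan")
    sd = float(np.std(products[ok], ddof=0) * 100) if ok.any() else float("nan")
    return {
        "mean_pct": mean,
        "sd_pct": sd,
        "n_pairs": len(products),
        "n_undefined": int((~ok).sum()),
        "n_significant": int(sum(f for f, o in zip(flags, ok) if o)),
        "fraction_significant": float(sum(flags) / len(flags)),
        "seed": seed,
    }
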
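"""Per-channel Lab color histograms — the SVM's feature representation.

Each channel (L*, a*, b*) is binned over a fixed range (L* over [0, 100],
a* and b* over [-128, 127]) so that histograms from different images share
bin edges and can be compared directly.  The concatenated per-channel
frequency vectors form the feature; normalized histograms (frequencies
summing to one per channel) remove the dependence on fin area and are the
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Fixed per-channel binning ranges: L* then a* then b*.
CHANNEL_RANGES = ((0.0, 100.0), (-128.0, 127.0), (-128.0, 127.0))

DEFAULT_BINS = 64


@dataclass(frozen=True)
class LabHistogram:
    """Per-channel Lab color histogram over fixed bin edges.

    ``counts`` has shape (3, B); row order is L*, a*, b*.  When
    ``normalized`` each row sums to 1, otherwise to the pixel count.
    """

    bins_per_channel: int
    edges: tuple[np.ndarray, np.ndarray, np.ndarray]
    counts: np.ndarray
    normalized: bool

    @property
    def feature(self) -> np.ndarray:
        """Concatenated length-3B feature vector (L*, a*, b* blocks)."""
        return self.counts.reshape(-1)


def channel_edges(bins: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fixed bin edges for the three Lab channels."""
    return tuple(np.linspace(lo, hi, bins + 1) for lo, hi in CHANNEL_RANGES)


def histogram(lab: np.ndarray, bins: int = DEFAULT_BINS, normalize: bool = True) -> LabHistogram:
    """Histogram a Lab image (or Lab pixel list) per channel.

    Parameters
    ----------
    lab : ndarray, shape (..., 3)
        Lab pixels; any leading shape is flattened.
    bins : int
        Number of bins per channel (>= 2).
    normalize : bool
        Divide counts by the pixel count so each channel sums to 1.

    Values outside the nominal channel range are clipped into the edge bins
    so that counts always conserve the pixel count.
    """
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    pixels = np.asarray(lab, dtype=float).reshape(-1, 3)
    if pixels.size == 0:
        raise ValueError("cannot histogram an empty image")
    edges = channel_edges(bins)
    counts = np.empty((3, bins), dtype=float)
    for c in range(3):
        lo, hi = CHANNEL_RANGES[c]
        vals = np.clip(pixels[:, c], lo, hi)
        counts[c], _ = np.histogram(vals, bins=edges[c])
    if normalize:
        counts /= pixels.shape[0]
    return LabHistogram(bins_per_channel=bins, edges=edges, counts=counts, normalized=normalize)


def histogram_distance(h1: LabHistogram, h2: LabHistogram) -> float:
    """Euclidean (L2) distance between two histogram feature vectors."""
    if h1.bins_per_channel != h2.bins_per_channel:
        raise ValueError(
            f"bin mismatch: {h1.bins_per_channel} vs {h2.bins_per_channel}"
        )
    if h1.normalized != h2.normalized:
        raise ValueError("cannot compare a normalized with an unnormalized histogram")
    return float(np.linalg.norm(h1.feature - h2.feature))


def feature_matrix(histograms: list[LabHistogram]) -> np.ndarray:
    """Stack histogram feature vectors into an (n_samples, 3B) matrix."""
    if not histograms:
        raise ValueError("no histograms given")
    bins = {h.bins_per_channel for h in histograms}
    if len(bins) != 1:
        raise ValueError(f"inconsistent bins across histograms: {sorted(bins)}")
    return np.stack([h.feature for h in histograms])


def extract_fin_features(samples, bins: int = DEFAULT_BINS, normalize: bool = True):
    """Fin-crop Lab histograms for a list of samples.

    Convenience for the SVM pathway: crops each sample's fin ROI, converts
    to Lab and histograms it.  Returns (ids, feature matrix, true-sex
    labels).
    """
    from finsex.imaging import crop_fin, rgb_to_lab

    hists = [histogram(rgb_to_lab(crop_fin(s)), bins=bins, normalize=normalize) for s in samples]
    ids = [s.id for s in samples]
    labels = np.array([s.true_sex for s in samples])
    return ids, feature_matrix(hists), labels


def features_to_frame(ids: list[str], histograms: list[LabHistogram]) -> pd.DataFrame:
    """Feature matrix as a DataFrame (id column + f000.. feature columns)."""
    X = feature_matrix(histograms)
    cols = [f"f{i:03d}" for i in range(X.shape[1])]
    frame = pd.DataFrame(X, columns=cols)
    frame.insert(0, "id", ids)
    return frame
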
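"""Chemical-space maps from MQN fingerprints.

Each molecule is described by the 42-dimensional molecular quantum numbers
(MQN) fingerprint — integer counts of atom, bond, polarity and topology
features.  A PCA is fitted on the raw, unscaled fingerprints; the first two
components are min–max normalized onto a ``w x h`` pixel grid and molecules
are bucketed per pixel.  Pixels are coloured in HSV on a black background:
hue encodes the bucket's mean descriptor value (swept dark blue -> cyan ->
green -> yellow -> orange -> red -> magenta), saturation is fixed at 1, and
value grows with the bucket's occupancy so sparse pixels fade into the
background while dense ones stand out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors
from sklearn.decomposition import PCA

__all__ = [
    "MqnPcaMap",
    "mqn_fingerprint",
    "build_map",
    "render",
    "default_value_rule",
    "default_hue_ramp",
]


def mqn_fingerprint(smiles: str) -> np.ndarray:
    """The 42-integer MQN descriptor vector (RDKit implementation)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    return np.asarray(rdMolDescriptors.MQNs_(mol), dtype=np.int64)


def default_value_rule(count_norm: np.ndarray) -> np.ndarray:
    """HSV value from [0,1]-normalized bucket counts.

    ``value = clip(max(0.25, 1 + log10(count_norm)), 0, 1)`` for occupied
    buckets, 0 (background) otherwise: a tenth of the maximum count already
    reaches full value, lower counts fade toward the 0.25 floor.
    """
    out = np.zeros_like(count_norm, dtype=np.float64)
    occ = count_norm > 0
    with np.errstate(divide="ignore"):
        out[occ] = np.clip(np.maximum(0.25, 1.0 + np.log10(count_norm[occ])), 0.0, 1.0)
    return out


def default_hue_ramp(t: np.ndarray) -> np.ndarray:
    """Map normalized descriptor in [0,1] to hue: blue (2/3) down through
    green/yellow/red (0) and on to magenta (5/6, i.e. -1/6 mod 1)."""
    return np.mod(2.0 / 3.0 - t * (2.0 / 3.0 + 1.0 / 6.0), 1.0)


@dataclass(frozen=True)
class MqnPcaMap:
    """A bucketed 2-D PCA projection of MQN space."""

    width: int
    height: int
    loadings: np.ndarray = field(repr=False)  # (42, 2)
    explained_variance_ratio: tuple[float, float]
    counts: np.ndarray = field(repr=False)  # (h, w) int
    mean_descriptor: np.ndarray = field(repr=False)  # (h, w), nan where empty
    descriptor_range: tuple[float, float]

    @property
    def buckets(self) -> dict[tuple[int, int], dict]:
        """Sparse view: (x, y) -> {count, mean_descriptor}."""
        ys, xs = np.nonzero(self.counts)
        return {
            (int(x), int(y)): {
                "count": int(self.counts[y, x]),
                "mean_descriptor": float(self.mean_descriptor[y, x]),
            }
            for y, x in zip(ys, xs)
        }


def build_map(
    smiles_with_descriptor: Sequence[tuple[str, float]],
    w: int,
    h: int,
) -> MqnPcaMap:
    """Fit PCA on raw MQN vectors and bucket molecules onto a w x h grid.

    No scaling or standardization is applied before the PCA.  Component
    signs are fixed by convention — each component is oriented so that its
    largest-magnitude loading is positive — making the map invariant to
    input order.  Degenerate input (all fingerprints identical) raises.
    """
    if len(smiles_with_descriptor) < 3:
        raise ValueError("need at least 3 molecules")
    smiles = [s for s, _ in smiles_with_descriptor]
    desc = np.array([float(v) for _, v in smiles_with_descriptor])
    if not np.all(np.isfinite(desc)):
        raise ValueError("descriptor values must be finite")
    X = np.array([mqn_fingerprint(s) for s in smiles], dtype=np.float64)
    if np.allclose(X, X[0]):
        raise ValueError("all fingerprints identical; PCA is degenerate")
    pca = PCA(n_components=2, svd_solver="full")
    proj = pca.fit_transform(X)
    components = pca.components_.copy()  # (2, 42)
    for c in range(2):
        j = np.argmax(np.abs(components[c]))
        if components[c, j] < 0:
            components[c] = -components[c]
            proj[:, c] = -proj[:, c]
    lo = proj.min(axis=0)
    span = proj.max(axis=0) - lo
    span[span == 0] = 1.0
    xy = (proj - lo) / span  # [0, 1]
    ix = np.minimum((xy[:, 0] * w).astype(int), w - 1)
    iy = np.minimum((xy[:, 1] * h).astype(int), h - 1)
    counts = np.zeros((h, w), dtype=np.int64)
    sums = np.zeros((h, w), dtype=np.float64)
    np.add.at(counts, (iy, ix), 1)
    np.add.at(sums, (iy, ix), desc)
    with np.errstate(invalid="ignore"):
        mean_desc = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return MqnPcaMap(
        width=w,
        height=h,
        loadings=components.T,
        explained_variance_ratio=(
            float(pca.explained_variance_ratio_[0]),
            float(pca.explained_variance_ratio_[1]),
        ),
        counts=counts,
        mean_descriptor=mean_desc,
        descriptor_range=(float(desc.min()), float(desc.max())),
    )


def render(
    mqn_map: MqnPcaMap,
    out: str | Path | None = None,
    *,
    value_rule: Callable[[np.ndarray], np.ndarray] = default_value_rule,
    hue_ramp: Callable[[np.ndarray], np.ndarray] = default_hue_ramp,
) -> np.ndarray:
    """Render the map to an (h, w, 3) RGB array; optionally save a PNG.

    Empty buckets are black.  Hue is the bucket's mean descriptor normalized
    over the map's descriptor range; value comes from the (max-normalized)
    count through ``value_rule``, which must be monotone non-decreasing.
    """
    from matplotlib.colors import hsv_to_rgb

    counts = mqn_map.counts.astype(np.float64)
    count_norm = counts / counts.max() if counts.max() > 0 else counts
    value = value_rule(count_norm)
    lo, hi = mqn_map.descriptor_range
    span = (hi - lo) or 1.0
    t = np.where(
        np.isnan(mqn_map.mean_descriptor),
        0.0,
        (np.nan_to_num(mqn_map.mean_descriptor, nan=lo) - lo) / span,
    )
    hsv = np.stack([hue_ramp(t), np.ones_like(value), value], axis=-1)
    rgb = hsv_to_rgb(hsv)
    if out is not None:
        import matplotlib.pyplot as plt

        plt.imsave(str(out), rgb, origin="lower")
    return rgb
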
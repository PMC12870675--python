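"""Phantom brain spaces: small 3D grids with grey-matter / isocortical masks
and a contiguous K-network parcellation.

A :class:`PhantomSpace` is the coordinate frame for every map in the
pipeline.  It emulates, at desk scale, the geometry the analysis assumes of
real data: a grey-matter mask, an isocortical subset of it, and an integer
label volume assigning each isocortical voxel to one of up to seven
functional networks (Yeo-style labels 1..K).  Labels are spatially
contiguous blocks so that planted effects form connected clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PhantomSpace", "make_phantom_space", "default_effect_region"]


class PhantomSizingError(ValueError):
    """Grid too small to host the requested parcellation."""


@dataclass(frozen=True)
class PhantomSpace:
    """3D grid with masks and network labels.

    Attributes
    ----------
    dims : tuple of int
        Voxels per axis.
    grey_mask : ndarray of bool, shape ``dims``
        Grey-matter mask (domain of weighted-degree).
    iso_mask : ndarray of bool, shape ``dims``
        Isocortical mask, a subset of ``grey_mask`` (domain of
        integration/segregation).
    labels : ndarray of int, shape ``dims``
        0 outside ``iso_mask``; network labels ``1..K`` inside.
    """

    dims: tuple[int, int, int]
    grey_mask: np.ndarray
    iso_mask: np.ndarray
    labels: np.ndarray
    n_networks: int = field(default=7)

    @property
    def n(self) -> int:
        """Number of grey-matter voxels."""
        return int(self.grey_mask.sum())

    @property
    def n_iso(self) -> int:
        return int(self.iso_mask.sum())

    @property
    def grey_index(self) -> np.ndarray:
        """(n, 3) integer coordinates of grey voxels, lexicographic order."""
        return np.argwhere(self.grey_mask)

    @property
    def iso_index(self) -> np.ndarray:
        return np.argwhere(self.iso_mask)

    @property
    def iso_labels(self) -> np.ndarray:
        """Per-isocortical-voxel label vector aligned with ``iso_index``."""
        return self.labels[self.iso_mask]

    @property
    def iso_in_grey(self) -> np.ndarray:
        """Boolean selector of isocortical voxels within the grey ordering."""
        return self.iso_mask[self.grey_mask]

    def validate(self) -> None:
        if self.grey_mask.shape != tuple(self.dims):
            raise ValueError("grey_mask shape does not match dims")
        if np.any(self.iso_mask & ~self.grey_mask):
            raise ValueError("iso_mask must be a subset of grey_mask")
        if np.any((self.labels > 0) != self.iso_mask):
            raise ValueError("labels must be nonzero exactly on iso_mask")
        present = np.unique(self.labels[self.iso_mask])
        if not np.array_equal(present, np.arange(1, self.n_networks + 1)):
            raise ValueError("every network label 1..K needs >= 1 voxel")


def make_phantom_space(
    dims: tuple[int, int, int] = (12, 12, 10),
    n_networks: int = 7,
    seed: int = 0,
) -> PhantomSpace:
    """Build a deterministic phantom space.

    The grey mask is the grid interior (a one-voxel background margin on
    every face).  The isocortical mask drops the bottom fifth of grey
    z-slices (a stand-in for cerebellum/subcortex, which carries
    weighted-degree but no network label).  The isocortical box is split
    into ``n_networks`` contiguous, near-equal blocks along the slowest
    axis; ``seed`` permutes which network id each block receives.

    Raises
    ------
    PhantomSizingError
        If the grid cannot host ``n_networks`` blocks of >= 4 voxels each.
    """
    dims = tuple(int(d) for d in dims)
    if len(dims) != 3 or any(d < 4 for d in dims):
        raise PhantomSizingError(f"each dim must be >= 4, got {dims}")
    if not (2 <= n_networks <= 7):
        raise ValueError(f"n_networks must be in 2..7, got {n_networks}")

    grey = np.zeros(dims, dtype=bool)
    grey[1:-1, 1:-1, 1:-1] = True

    # isocortex: exclude the lowest ~20% of grey z-slices (>= 1 slice)
    z_lo, z_hi = 1, dims[2] - 1
    n_z = z_hi - z_lo
    drop = max(1, int(np.ceil(0.2 * n_z)))
    iso = grey.copy()
    iso[:, :, : z_lo + drop] = False
    if iso.sum() < 4 * n_networks:
        raise PhantomSizingError(
            f"{dims} hosts only {int(iso.sum())} isocortical voxels; "
            f"need >= {4 * n_networks} for {n_networks} contiguous networks"
        )

    # contiguous blocks: chunk the lexicographically ordered iso voxels.
    # A lex-order run inside a box is 26-connected (partial planes attach
    # to their neighbouring full planes).
    coords = np.argwhere(iso)  # already lexicographic (x, y, z)
    n_iso = len(coords)
    bounds = np.linspace(0, n_iso, n_networks + 1).round().astype(int)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_networks) + 1
    labels = np.zeros(dims, dtype=np.int32)
    for k in range(n_networks):
        block = coords[bounds[k] : bounds[k + 1]]
        labels[block[:, 0], block[:, 1], block[:, 2]] = order[k]

    space = PhantomSpace(dims, grey, iso, labels, n_networks)
    space.validate()
    return space


def default_effect_region(
    space: PhantomSpace, network: int, n_voxels: int = 40
) -> np.ndarray:
    """Compact blob of ``n_voxels`` isocortical voxels of one network.

    Returns the (m, 3) coordinates of the ``n_voxels`` member voxels of
    ``network`` closest to the network's centroid — a connected
    "insula-like" target for planting effects.
    """
    members = np.argwhere(space.labels == network)
    if len(members) == 0:
        raise ValueError(f"network {network} has no voxels")
    n_voxels = min(n_voxels, len(members))
    centroid = members.mean(axis=0)
    d = np.linalg.norm(members - centroid, axis=1)
    return members[np.argsort(d, kind="stable")[:n_voxels]]
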
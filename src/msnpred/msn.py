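"""Morphometric similarity networks (MSNs) and their nodal graph metrics.

An individual MSN treats each cortical region as a node carrying a vector of
morphometric features (7 by default). Features are z-scored *across regions*
within a subject, and the edge between two regions is the Pearson correlation
of their feature vectors. Networks are optionally thresholded to a target
density by keeping the strongest absolute edge weights, and summarised per
node by degree and normalized strength.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lexicon import n_possible_edges


class ZeroVarianceError(ValueError):
    """A feature (or region vector) is constant where variation is required."""


@dataclass
class MSNetwork:
    """A subject's symmetric morphometric similarity matrix.

    ``density`` is None for the unthresholded network; after thresholding it
    records the target edge density in (0, 1].
    """

    subject_id: str
    regions: tuple[str, ...]
    matrix: np.ndarray
    density: float | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.regions)
        if m.shape != (n, n):
            raise ValueError(f"matrix shape {m.shape} does not match {n} regions")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if np.any(np.abs(np.diag(m)) > 1e-12):
            raise ValueError("diagonal must be zero")
        if np.any(np.abs(m) > 1 + 1e-12):
            raise ValueError("similarity values must lie in [-1, 1]")
        self.matrix = m

    @property
    def retained_edge_count(self) -> int:
        iu = np.triu_indices(len(self.regions), k=1)
        return int(np.count_nonzero(self.matrix[iu]))


@dataclass
class NodalMetricsTable:
    """Per subject x region degree and normalized strength, plus the
    per-subject global mean strength."""

    degree: pd.DataFrame
    strength: pd.DataFrame
    global_strength: pd.Series = field(default=None)  # type: ignore[assignment]
    density: float | None = None

    def __post_init__(self) -> None:
        if self.global_strength is None:
            self.global_strength = self.strength.mean(axis=1)
            self.global_strength.name = "global_mean_strength"

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.degree.columns)

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(self.degree.index)


def zscore_within_subject(features: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Z-score each feature column across regions within one subject.

    Parameters
    ----------
    features : (n_regions, n_features) array
    ddof : 0 for population SD, 1 (default) for sample SD. MSN edge values are
        invariant to this choice because Pearson correlation is scale-free in
        each column; the default is fixed only so intermediate files reproduce.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D region x feature matrix")
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=ddof)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ZeroVarianceError(
            f"feature column(s) {bad.tolist()} constant across regions; z-score undefined"
        )
    return (x - mu) / sd


def build_msn(
    z: np.ndarray,
    subject_id: str = "",
    regions: tuple[str, ...] | None = None,
    on_degenerate: str = "zero",
) -> MSNetwork:
    """Pearson-correlate every pair of region feature vectors.

    A region whose z-scored feature vector has zero variance yields undefined
    correlations; its edges are set to 0 with a warning (``on_degenerate=
    'zero'``) or raise (``'error'``).
    """
    z = np.asarray(z, dtype=float)
    n = z.shape[0]
    if regions is None:
        from .lexicon import generic_regions

        regions = generic_regions(n)
    row_sd = z.std(axis=1)
    degenerate = np.flatnonzero(row_sd == 0)
    if degenerate.size and on_degenerate == "error":
        raise ZeroVarianceError(
            f"region vector(s) {[regions[i] for i in degenerate]} have zero variance"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(z)
    if degenerate.size:
        warnings.warn(
            f"{degenerate.size} region vector(s) with zero variance; edges set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        corr[degenerate, :] = 0.0
        corr[:, degenerate] = 0.0
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    return MSNetwork(subject_id=subject_id, regions=tuple(regions), matrix=corr)


def threshold_by_density(net: MSNetwork, density: float) -> MSNetwork:
    """Keep the ``round(density * n_edges)`` strongest absolute edges.

    Retained edges keep their signed weights. Ties in |weight| are broken
    deterministically by ascending (row, column) region index, so the retained
    edge set is a function of the matrix alone and edge sets are nested across
    densities.
    """
    if not 0 < density <= 1:
        raise ValueError(f"density must lie in (0, 1], got {density}")
    n = len(net.regions)
    keep = int(np.rint(density * n_possible_edges(n)))
    iu, ju = np.triu_indices(n, k=1)
    w = net.matrix[iu, ju]
    # primary key: descending |w|; then ascending i, then j
    order = np.lexsort((ju, iu, -np.abs(w)))
    kept = order[:keep]
    out = np.zeros_like(net.matrix)
    out[iu[kept], ju[kept]] = w[kept]
    out = out + out.T
    return MSNetwork(
        subject_id=net.subject_id, regions=net.regions, matrix=out, density=density
    )


def nodal_degree(net: MSNetwork) -> np.ndarray:
    """Number of surviving edges at each node (integer per region)."""
    off = net.matrix.copy()
    np.fill_diagonal(off, 0.0)
    return np.count_nonzero(off, axis=1)


def nodal_strength_normalized(net: MSNetwork, signed: bool = False) -> np.ndarray:
    """Mean similarity weight over each node's retained edges.

    Defined as the sum of retained edge weights at the node divided by its
    degree; by default the *absolute* weights are summed (strength as the
    magnitude of similarity), with ``signed=True`` keeping signs. Zero-degree
    nodes get strength 0.
    """
    deg = nodal_degree(net)
    w = net.matrix if signed else np.abs(net.matrix)
    total = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(deg > 0, total / np.maximum(deg, 1), 0.0)
    return s


def global_mean_strength(strengths: np.ndarray) -> float:
    """Unweighted mean of the nodal strengths (one scalar per subject)."""
    return float(np.mean(strengths))


def compute_nodal_metrics(
    networks: list[MSNetwork], signed_strength: bool = False
) -> NodalMetricsTable:
    """Stack per-subject degree / strength into tidy tables."""
    if not networks:
        raise ValueError("no networks supplied")
    regions = networks[0].regions
    densities = {net.density for net in networks}
    if len(densities) != 1:
        raise ValueError("networks computed at mixed densities")
    deg_rows, str_rows, ids = [], [], []
    for net in networks:
        if net.regions != regions:
            raise ValueError(f"region mismatch for subject {net.subject_id}")
        deg_rows.append(nodal_degree(net))
        str_rows.append(nodal_strength_normalized(net, signed=signed_strength))
        ids.append(net.subject_id)
    deg = pd.DataFrame(deg_rows, index=ids, columns=list(regions))
    stren = pd.DataFrame(str_rows, index=ids, columns=list(regions))
    return NodalMetricsTable(degree=deg, strength=stren, density=next(iter(densities)))


def metrics_from_features(
    values: np.ndarray,
    subjects: list[str],
    regions: tuple[str, ...],
    density: float | None,
    signed_strength: bool = False,
) -> NodalMetricsTable:
    """Full per-cohort pipeline: z-score, correlate, threshold, summarise.

    ``values`` is the (n_subjects, n_regions, n_features) block of a feature
    table; ``density=None`` computes metrics on the unthresholded network.
    """
    nets = []
    for sid, mat in zip(subjects, values):
        z = zscore_within_subject(mat)
        net = build_msn(z, subject_id=sid, regions=regions)
        if density is not None:
            net = threshold_by_density(net, density)
        nets.append(net)
    return compute_nodal_metrics(nets, signed_strength=signed_strength)
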
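"""Region and feature lexicons.

The cortical parcellation is the Desikan-Killiany atlas: 34 regions per
hemisphere, 68 nodes total. The canonical region order (left hemisphere
first, then alphabetical within hemisphere) is shipped as a versioned text
file so that matrices and metric tables are comparable across runs and
machines.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

#: The seven regional morphometric features, in canonical order.
FEATURES: tuple[str, ...] = (
    "surface_area",
    "curvature_index",
    "folding_index",
    "gaussian_curvature",
    "mean_curvature",
    "cortical_thickness",
    "cortical_volume",
)

#: Freesurfer aparcstats2table measure names -> canonical feature names.
FREESURFER_MEASURES: dict[str, str] = {
    "area": "surface_area",
    "curvind": "curvature_index",
    "foldind": "folding_index",
    "gauscurv": "gaussian_curvature",
    "meancurv": "mean_curvature",
    "thickness": "cortical_thickness",
    "volume": "cortical_volume",
}


@lru_cache(maxsize=1)
def dk_regions() -> tuple[str, ...]:
    """The 68 Desikan-Killiany region labels in canonical order."""
    text = resources.files("msnpred.data").joinpath("dk_lexicon.txt").read_text()
    regions = tuple(
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )
    if len(regions) != 68:
        raise RuntimeError(f"lexicon file lists {len(regions)} regions, expected 68")
    return regions


def generic_regions(n: int) -> tuple[str, ...]:
    """Generic region labels for reduced-size simulations (``r01`` ...)."""
    width = max(2, len(str(n)))
    return tuple(f"r{i + 1:0{width}d}" for i in range(n))


def n_possible_edges(n_regions: int) -> int:
    """Number of undirected edges in a complete graph: n*(n-1)/2 (2278 for 68)."""
    return n_regions * (n_regions - 1) // 2
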
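"""Readers and writers for feature tables, cohort metadata and networks.

The canonical on-disk feature format is a wide CSV/TSV with one row per
subject and one column per ``<region>_<feature>`` pair (68 regions x 7
features). A Freesurfer ``aparcstats2table`` dialect is also accepted for the
per-hemisphere stats-table exports. Readers enforce completeness: a missing
region x feature cell is an error, never silently imputed.

Also houses the executive-function summary score: the sum of seven
age-scaled neuropsychological subtest scores (each on the M=10, SD=3 metric),
with flagged subtests reverse-scored by mirroring about the scale mean
(reversed = 20 - score) so that higher always means better performance.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .lexicon import FEATURES, FREESURFER_MEASURES, dk_regions
from .msn import MSNetwork

GROUPS = ("TBI", "control")
COHORT_COLUMNS = (
    "group",
    "sex",
    "age_at_scan",
    "age_at_injury",
    "injury_scan_interval",
    "severity",
    "eTIV",
    "brief_gec",
    "ef_summary",
)


def feature_array(
    wide: pd.DataFrame,
    regions: tuple[str, ...],
    features: tuple[str, ...] = FEATURES,
) -> np.ndarray:
    """Reshape a validated wide table into (n_subjects, n_regions, n_features)."""
    cols = [f"{r}_{f}" for r in regions for f in features]
    return wide[cols].to_numpy(dtype=float).reshape(len(wide), len(regions), len(features))


def _split_column(col: str, features: tuple[str, ...]) -> tuple[str, str] | None:
    for feat in features:
        suffix = "_" + feat
        if col.endswith(suffix):
            return col[: -len(suffix)], feat
    return None


def write_feature_table(wide: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    wide.to_csv(path, sep=sep, index_label="subject_id")


def read_feature_table(
    path: str | Path,
    dialect: str = "wide_csv",
    regions: tuple[str, ...] | None = None,
    features: tuple[str, ...] = FEATURES,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a regional morphometric feature table.

    ``dialect='wide_csv'`` reads the canonical wide format. Unknown region
    labels, missing region x feature columns and non-numeric cells are all
    hard errors. Returns the wide DataFrame in canonical column order.
    """
    if dialect != "wide_csv":
        raise ValueError(f"unknown dialect {dialect!r} (use read_aparcstats_tables "
                         "for the Freesurfer stats-table export)")
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    raw = pd.read_csv(path, sep=sep, index_col="subject_id")

    parsed: dict[str, tuple[str, str]] = {}
    for col in raw.columns:
        hit = _split_column(col, features)
        if hit is None:
            raise ValueError(f"column {col!r} does not end in a known feature name")
        parsed[col] = hit
    seen_regions = {r for r, _ in parsed.values()}
    if regions is None:
        lexicon = set(dk_regions())
        unknown = sorted(seen_regions - lexicon)
        if unknown:
            raise ValueError(f"unknown region label(s): {unknown}")
        regions = tuple(r for r in dk_regions() if r in seen_regions) if len(
            seen_regions
        ) < 68 else dk_regions()
        if len(seen_regions) < 68:
            missing_regions = sorted(lexicon - seen_regions)
            raise ValueError(f"feature table missing region(s): {missing_regions}")
    else:
        unknown = sorted(seen_regions - set(regions))
        if unknown:
            raise ValueError(f"unknown region label(s): {unknown}")

    expected = [f"{r}_{f}" for r in regions for f in features]
    missing = [c for c in expected if c not in raw.columns]
    if missing:
        raise ValueError(f"feature table missing column(s): {missing}")
    table = raw[expected].copy()
    for col in expected:
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[vals.isna() & table[col].notna()]
        if len(bad):
            raise ValueError(f"non-numeric cell at subject {bad[0]!r}, column {col!r}")
        if vals.isna().any():
            sid = table.index[vals.isna()][0]
            raise ValueError(f"missing value at subject {sid!r}, column {col!r}")
        table[col] = vals.astype(float)
    dup = table.index[table.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject_id {dup[0]!r}")
    return table


def read_aparcstats_tables(
    files: dict[str, dict[str, str | Path]],
    regions: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Assemble the wide table from Freesurfer ``aparcstats2table`` exports.

    ``files`` maps a Freesurfer measure name (``area``, ``thickness``,
    ``volume``, ``meancurv``, ``gauscurv``, ``foldind``, ``curvind``) to
    ``{"lh": path, "rh": path}``. Each file is the tab-separated table whose
    columns are ``<hemi>_<region>_<measure>``.
    """
    frames = []
    for measure, hemi_files in files.items():
        if measure not in FREESURFER_MEASURES:
            raise ValueError(f"unknown Freesurfer measure {measure!r}")
        feature = FREESURFER_MEASURES[measure]
        for hemi, path in hemi_files.items():
            tab = pd.read_csv(path, sep="\t", index_col=0)
            tab.index.name = "subject_id"
            rename = {}
            for col in tab.columns:
                if col.lower().startswith(("brainsegvol", "etiv", "eTIV".lower())):
                    continue  # volume summary columns appended by Freesurfer
                if not col.endswith("_" + measure) or not col.startswith(hemi + "_"):
                    continue
                region = col[: -len("_" + measure)]
                rename[col] = f"{region}_{feature}"
            frames.append(tab[list(rename)].rename(columns=rename))
    wide = pd.concat(frames, axis=1)
    if wide.isna().any().any():
        sid = wide.index[wide.isna().any(axis=1)][0]
        raise ValueError(f"subject {sid!r} missing in at least one stats table")
    if regions is None:
        regions = dk_regions()
    expected = [f"{r}_{f}" for r in regions for f in FEATURES]
    missing = [c for c in expected if c not in wide.columns]
    if missing:
        raise ValueError(f"stats tables missing column(s): {missing}")
    return wide[expected]


def write_cohort_table(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index_label="subject_id")


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read and validate the cohort metadata table.

    Enforces unique subject ids, valid group labels, positive ages and eTIV;
    drops (with a warning) injury fields recorded for controls; unparseable
    optional fields become missing values.
    """
    raw = pd.read_csv(path, dtype={"subject_id": str}).set_index("subject_id")
    dup = raw.index[raw.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject_id {dup[0]!r} in cohort table")
    bad_groups = set(raw["group"].unique()) - set(GROUPS)
    if bad_groups:
        raise ValueError(f"group label(s) outside {GROUPS}: {sorted(bad_groups)}")
    bad_sex = set(raw["sex"].unique()) - {"M", "F"}
    if bad_sex:
        raise ValueError(f"sex label(s) outside {{'M','F'}}: {sorted(bad_sex)}")
    for col in ("age_at_scan", "eTIV"):
        raw[col] = pd.to_numeric(raw[col], errors="raise")
        if (raw[col] <= 0).any():
            sid = raw.index[raw[col] <= 0][0]
            raise ValueError(f"nonpositive {col} for subject {sid!r}")
    for col in ("age_at_injury", "injury_scan_interval", "brief_gec", "ef_summary"):
        if col in raw.columns:
            raw[col] = pd.to_numeric(raw[col], errors="coerce")
    if "severity" in raw.columns:  # pandas reads the literal "NA" as missing
        raw["severity"] = raw["severity"].fillna("NA")
    for col in ("age_at_injury", "injury_scan_interval"):
        if col in raw.columns:
            leak = (raw["group"] == "control") & raw[col].notna()
            if leak.any():
                warnings.warn(
                    f"control subject(s) {list(raw.index[leak])} carry {col}; "
                    "field dropped",
                    UserWarning,
                    stacklevel=2,
                )
                raw.loc[leak, col] = np.nan
    return raw


def compute_ef_summary(
    subtest_scores, reverse_flags, scale_max: float = 20.0
) -> float:
    """Sum of the 7 age-scaled subtest scores, reverse-scoring flagged ones.

    Each score lives on the age-scaled metric (mean 10, SD 3); a reversed
    subtest contributes ``20 - score`` so higher totals always mean better
    performance. Which subtests to reverse (typically the time-taken
    measures) is the caller's configuration.
    """
    scores = np.asarray(subtest_scores, dtype=float)
    flags = np.asarray(reverse_flags, dtype=bool)
    if scores.shape != (7,) or flags.shape != (7,):
        raise ValueError(
            f"expected exactly 7 subtest scores and 7 reverse flags, "
            f"got {scores.shape} and {flags.shape}"
        )
    if np.any((scores < 0) | (scores > scale_max)):
        warnings.warn(
            "subtest score outside the plausible [0, 20] age-scaled range",
            UserWarning,
            stacklevel=2,
        )
    adjusted = np.where(flags, scale_max - scores, scores)
    return float(adjusted.sum())


def write_network(net: MSNetwork, path: str | Path, fmt: str = "dense") -> None:
    """Serialize a network as a dense labelled CSV or a TSV edge list."""
    path = Path(path)
    if fmt == "dense":
        df = pd.DataFrame(net.matrix, index=net.regions, columns=net.regions)
        df.to_csv(path, index_label="region", float_format="%.17g")
    elif fmt == "edgelist":
        iu, ju = np.triu_indices(len(net.regions), k=1)
        w = net.matrix[iu, ju]
        keep = w != 0
        df = pd.DataFrame(
            {
                "region_a": np.asarray(net.regions)[iu[keep]],
                "region_b": np.asarray(net.regions)[ju[keep]],
                "weight": w[keep],
            }
        )
        with open(path, "w") as fh:
            fh.write(f"# subject_id={net.subject_id}\n")
            fh.write(f"# density={net.density}\n")
            fh.write(f"# regions={','.join(net.regions)}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(
    path: str | Path,
    fmt: str = "dense",
    subject_id: str = "",
    density: float | None = None,
) -> MSNetwork:
    path = Path(path)
    if fmt == "dense":
        df = pd.read_csv(path, index_col="region")
        regions = tuple(df.index)
        if tuple(df.columns) != regions:
            raise ValueError("dense network rows and columns disagree on regions")
        m = df.to_numpy(dtype=float)
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("dense network matrix is not symmetric")
    elif fmt == "edgelist":
        meta: dict[str, str] = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for line in lines:
            if not line.startswith("#"):
                break
            body_start += 1
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val
        from io import StringIO

        df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t")
        regions = tuple(meta["regions"].split(","))
        if not subject_id:
            subject_id = meta.get("subject_id", "")
        if density is None and meta.get("density", "None") != "None":
            density = float(meta["density"])
        index = {r: i for i, r in enumerate(regions)}
        m = np.zeros((len(regions), len(regions)))
        for a, b, w in df.itertuples(index=False):
            if a not in index or b not in index:
                raise ValueError(f"edge references unknown region {a!r} or {b!r}")
            m[index[a], index[b]] = m[index[b], index[a]] = w
    else:
        raise ValueError(f"unknown network format {fmt!r}")
    if len(set(regions)) != len(regions):
        raise ValueError("duplicate region labels in network file")
    return MSNetwork(subject_id=subject_id, regions=regions, matrix=m, density=density)
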
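"""Core containers, file I/O, and quality-control filters for microbiome tables.

The analysis operates on four kinds of objects: an ASV count table
(samples x amplicon sequence variants), per-sample host metadata, rooted
phylogenies (host and microbial, handled as :class:`dendropy.Tree`), and
labelled distance matrices.  All on-disk formats are plain tab-separated
text or Newick.

QC follows the standard amplicon workflow: drop every ASV detected in a
PCR negative control, drop samples below a minimum read depth, then
rarefy each remaining sample to a common depth by sampling reads without
replacement.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "AsvTable",
    "SampleInfo",
    "DistanceMatrix",
    "TraitMatrix",
    "TipNameMap",
    "FormatError",
    "read_asv_table",
    "write_asv_table",
    "read_metadata",
    "write_metadata",
    "metadata_to_frame",
    "read_newick",
    "write_newick",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_traits",
    "write_traits",
    "prune_and_rename",
    "remove_control_asvs",
    "filter_min_depth",
    "rarefy",
    "derive_seed",
]

METADATA_COLUMNS = (
    "sample_id",
    "host_species",
    "host_genus",
    "host_family",
    "site",
    "is_control",
)

DIET_ITEMS = ("fruit", "leaves", "insects", "bamboo", "gum", "flowers")


class FormatError(ValueError):
    """Raised when an input file or in-memory object violates a format contract."""


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise FormatError(f"duplicate {what} identifier: {lab!r}")
        seen.add(lab)


class AsvTable:
    """Integer count matrix of samples (rows) by ASVs (columns).

    Parameters
    ----------
    counts:
        Non-negative integer matrix, shape ``(n_samples, n_asvs)``.
    sample_ids, asv_ids:
        Unique row and column labels, in matrix order.
    """

    def __init__(
        self,
        counts: np.ndarray,
        sample_ids: Sequence[str],
        asv_ids: Sequence[str],
    ) -> None:
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix")
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise FormatError("counts must be integers")
        counts = counts.astype(np.int64, copy=True)
        if counts.size and counts.min() < 0:
            i, j = np.argwhere(counts < 0)[0]
            raise FormatError(
                f"negative count at sample {sample_ids[i]!r}, ASV {asv_ids[j]!r}"
            )
        sample_ids = [str(s) for s in sample_ids]
        asv_ids = [str(a) for a in asv_ids]
        if counts.shape != (len(sample_ids), len(asv_ids)):
            raise FormatError(
                f"label/matrix shape mismatch: counts {counts.shape}, "
                f"{len(sample_ids)} samples, {len(asv_ids)} ASVs"
            )
        _check_unique(sample_ids, "sample")
        _check_unique(asv_ids, "ASV")
        self.counts = counts
        self.sample_ids = list(sample_ids)
        self.asv_ids = list(asv_ids)

    # -- basic protocol ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_asvs(self) -> int:
        return len(self.asv_ids)

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AsvTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.asv_ids == other.asv_ids
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:
        return f"AsvTable({self.n_samples} samples x {self.n_asvs} ASVs)"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.asv_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AsvTable":
        return cls(frame.to_numpy(), list(frame.index), list(frame.columns))

    def select_samples(self, keep: Sequence[str]) -> "AsvTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in keep if s not in idx]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        rows = [idx[s] for s in keep]
        return AsvTable(self.counts[rows], list(keep), self.asv_ids)

    def select_asvs(self, keep: Sequence[str]) -> "AsvTable":
        idx = {a: j for j, a in enumerate(self.asv_ids)}
        missing = [a for a in keep if a not in idx]
        if missing:
            raise KeyError(f"unknown ASVs: {missing}")
        cols = [idx[a] for a in keep]
        return AsvTable(self.counts[:, cols], self.sample_ids, list(keep))

    def drop_empty_asvs(self) -> "AsvTable":
        """Remove ASVs with zero total count across all samples."""
        keep = self.counts.sum(axis=0) > 0
        return AsvTable(
            self.counts[:, keep],
            self.sample_ids,
            [a for a, k in zip(self.asv_ids, keep) if k],
        )


@dataclass(frozen=True)
class SampleInfo:
    """Host metadata for a single sample."""

    sample_id: str
    host_species: str
    host_genus: str
    host_family: str
    site: str
    is_control: bool = False

    def __post_init__(self) -> None:
        if not self.is_control:
            for f in ("host_species", "host_genus", "host_family"):
                if not getattr(self, f):
                    raise FormatError(
                        f"non-control sample {self.sample_id!r} has empty {f}"
                    )


def metadata_to_frame(meta: Iterable[SampleInfo]) -> pd.DataFrame:
    rows = list(meta)
    _check_unique([m.sample_id for m in rows], "sample")
    frame = pd.DataFrame(
        [
            (m.sample_id, m.host_species, m.host_genus, m.host_family, m.site, m.is_control)
            for m in rows
        ],
        columns=list(METADATA_COLUMNS),
    )
    return frame.set_index("sample_id", drop=False)


def _metadata_from_frame(frame: pd.DataFrame) -> list[SampleInfo]:
    missing = [c for c in METADATA_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"metadata missing required columns: {missing}")
    out = []
    for _, r in frame.iterrows():
        flag = r["is_control"]
        if isinstance(flag, str):
            flag = flag.strip().lower() in ("true", "1", "yes")
        out.append(
            SampleInfo(
                sample_id=str(r["sample_id"]),
                host_species="" if pd.isna(r["host_species"]) else str(r["host_species"]),
                host_genus="" if pd.isna(r["host_genus"]) else str(r["host_genus"]),
                host_family="" if pd.isna(r["host_family"]) else str(r["host_family"]),
                site="" if pd.isna(r["site"]) else str(r["site"]),
                is_control=bool(flag),
            )
        )
    _check_unique([m.sample_id for m in out], "sample")
    return out


class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal.

    Symmetry is enforced to 1e-12; values must be non-negative.
    """

    def __init__(self, values: np.ndarray, labels: Sequence[str]) -> None:
        values = np.asarray(values, dtype=float)
        labels = [str(x) for x in labels]
        n = len(labels)
        if values.shape != (n, n):
            raise FormatError(f"distance matrix shape {values.shape} != ({n}, {n})")
        _check_unique(labels, "distance-matrix")
        if np.isnan(values).any():
            raise FormatError("distance matrix contains NaN")
        if not np.allclose(values, values.T, atol=1e-12, rtol=0.0):
            raise FormatError("distance matrix is not symmetric within 1e-12")
        if n and np.abs(np.diag(values)).max() > 1e-12:
            raise FormatError("distance matrix diagonal is not zero")
        if n and values.min() < 0:
            raise FormatError("distance matrix has negative entries")
        values = 0.5 * (values + values.T)
        np.fill_diagonal(values, 0.0)
        self.values = values
        self.labels = labels

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy 'condensed' order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = {lab: i for i, lab in enumerate(self.labels)}
        missing = [x for x in labels if x not in idx]
        if missing:
            raise KeyError(f"labels not in distance matrix: {missing}")
        order = [idx[x] for x in labels]
        return DistanceMatrix(self.values[np.ix_(order, order)], list(labels))

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        i = self.labels.index(a)
        j = self.labels.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def __repr__(self) -> str:
        return f"DistanceMatrix({self.n} labels)"


class TraitMatrix:
    """Per-species numeric trait table (species x traits).

    When the traits are the six food-item proportions (fruit, leaves,
    insects, bamboo, gum, flowers) each species' proportions must not sum
    above 1 (+1e-6 slack).
    """

    def __init__(
        self,
        values: np.ndarray,
        species_ids: Sequence[str],
        trait_names: Sequence[str],
    ) -> None:
        values = np.asarray(values, dtype=float)
        species_ids = [str(s) for s in species_ids]
        trait_names = [str(t) for t in trait_names]
        if values.shape != (len(species_ids), len(trait_names)):
            raise FormatError("trait matrix shape does not match labels")
        _check_unique(species_ids, "species")
        _check_unique(trait_names, "trait")
        self.values = values
        self.species_ids = species_ids
        self.trait_names = trait_names
        diet = [t for t in trait_names if t in DIET_ITEMS]
        if set(diet) == set(DIET_ITEMS):
            sums = self.to_frame()[list(DIET_ITEMS)].sum(axis=1)
            if (sums > 1.0 + 1e-6).any():
                bad = sums[sums > 1 + 1e-6].index.tolist()
                raise FormatError(f"diet proportions sum above 1 for: {bad}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species_ids, columns=self.trait_names)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TraitMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns))

    def column(self, name: str) -> pd.Series:
        return self.to_frame()[name]

    def __repr__(self) -> str:
        return f"TraitMatrix({len(self.species_ids)} species x {len(self.trait_names)} traits)"


class TipNameMap:
    """Injective mapping from tree tip labels to study taxon labels.

    Used to graft study taxa onto their closest available relatives in a
    published phylogeny (e.g. relabelling *Phaner furcifer* as the sampled
    *Phaner pallescens*).
    """

    def __init__(self, pairs: Mapping[str, str]) -> None:
        pairs = {str(k): str(v) for k, v in pairs.items()}
        values = list(pairs.values())
        if len(set(values)) != len(values):
            raise FormatError("tip-name map is not injective")
        self.forward = dict(pairs)
        self.backward = {v: k for k, v in pairs.items()}

    def apply(self, label: str) -> str:
        return self.forward.get(label, label)

    def invert(self, label: str) -> str:
        return self.backward.get(label, label)

    def __len__(self) -> int:
        return len(self.forward)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_asv_table(path, orientation: str = "samples_as_rows") -> AsvTable:
    """Read a tab-separated count matrix.

    ``orientation`` declares what the file rows are: ``"samples_as_rows"``
    or ``"features_as_rows"`` (the QIIME2 export convention, with an
    optional leading ``#OTU ID`` token).  The in-memory table is always
    samples x ASVs.
    """
    if orientation not in ("samples_as_rows", "features_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    frame = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    frame.index = frame.index.astype(str)
    if frame.index.name and str(frame.index.name).lstrip("#").strip() in (
        "OTU ID",
        "ASV ID",
    ):
        pass  # tolerated header token
    if orientation == "features_as_rows":
        frame = frame.T
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise FormatError(f"duplicate sample identifier: {dup!r}")
    if frame.columns.duplicated().any():
        dup = frame.columns[frame.columns.duplicated()][0]
        raise FormatError(f"duplicate ASV identifier: {dup!r}")
    arr = frame.to_numpy()
    bad = ~np.isfinite(arr.astype(float)) | (np.mod(arr.astype(float), 1) != 0) | (
        arr.astype(float) < 0
    )
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"cell at row {frame.index[i]!r}, column {frame.columns[j]!r} "
            "is not a non-negative integer"
        )
    return AsvTable.from_frame(frame)


def write_asv_table(table: AsvTable, path, orientation: str = "samples_as_rows") -> None:
    frame = table.to_frame()
    if orientation == "features_as_rows":
        frame = frame.T
        frame.index.name = "#OTU ID"
    else:
        frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t")


def read_metadata(path) -> list[SampleInfo]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return _metadata_from_frame(frame)


def write_metadata(meta: Iterable[SampleInfo], path) -> None:
    metadata_to_frame(meta).to_csv(path, sep="\t", index=False)


def read_newick(source) -> dendropy.Tree:
    """Parse a rooted Newick tree (path or string) and validate it.

    Tip labels must be unique; negative branch lengths are rejected.
    Underscores in unquoted labels are preserved as-is.
    """
    try:
        if isinstance(source, str) and source.lstrip().startswith("("):
            tree = dendropy.Tree.get(
                data=source, schema="newick", preserve_underscores=True
            )
        else:
            tree = dendropy.Tree.get(
                path=str(source), schema="newick", preserve_underscores=True
            )
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        raise FormatError(f"invalid Newick tree: {exc}") from exc
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    _check_unique(labels, "tree tip")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise FormatError("negative branch length in tree")
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(newick_string(tree) + "\n")


def newick_string(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def read_distance_matrix(path) -> DistanceMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if list(frame.index.astype(str)) != list(frame.columns.astype(str)):
        raise FormatError("distance matrix row and column labels differ")
    return DistanceMatrix(frame.to_numpy(dtype=float), list(frame.index.astype(str)))


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    dm.to_frame().to_csv(path, sep="\t")


def read_traits(path) -> TraitMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    return TraitMatrix.from_frame(frame)


def write_traits(traits: TraitMatrix, path) -> None:
    frame = traits.to_frame()
    frame.index.name = "species_id"
    frame.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Tree surgery
# ---------------------------------------------------------------------------

def prune_and_rename(
    tree: dendropy.Tree,
    keep: Iterable[str],
    name_map: TipNameMap | None = None,
) -> dendropy.Tree:
    """Rename tips via ``name_map`` then prune the tree to ``keep``.

    Path lengths among the retained tips are unchanged.  Raises
    ``KeyError`` listing any requested taxon that cannot be resolved.
    """
    keep = [str(k) for k in keep]
    tree = tree.clone(depth=1)
    if name_map is not None:
        for leaf in tree.leaf_node_iter():
            leaf.taxon.label = name_map.apply(leaf.taxon.label)
    available = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = sorted(set(keep) - available)
    if missing:
        raise KeyError(f"taxa not resolvable in tree: {missing}")
    taxa = [t for t in tree.taxon_namespace if t.label in set(keep)]
    tree.retain_taxa(taxa)
    # drop degree-2 root introduced by pruning so path lengths stay additive
    tree.suppress_unifurcations()
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def remove_control_asvs(table: AsvTable, meta: Iterable[SampleInfo]) -> AsvTable:
    """Drop every ASV observed in a PCR negative control, then drop the controls.

    A blanket removal: any ASV with a nonzero count in any control sample
    is excluded from all samples.  If the metadata contains no controls the
    table is returned unchanged with a warning.
    """
    meta = list(meta)
    by_id = {m.sample_id: m for m in meta}
    controls = [s for s in table.sample_ids if by_id.get(s, None) and by_id[s].is_control]
    if not controls:
        warnings.warn("no control samples present; control filtering is a no-op")
        return table
    ctrl_rows = table.select_samples(controls).counts
    contaminated = ctrl_rows.sum(axis=0) > 0
    keep_asvs = [a for a, bad in zip(table.asv_ids, contaminated) if not bad]
    if not keep_asvs:
        warnings.warn("all ASVs were observed in controls; feature set is empty")
    keep_samples = [s for s in table.sample_ids if s not in set(controls)]
    out = table.select_samples(keep_samples)
    return AsvTable(
        out.counts[:, ~contaminated] if out.n_samples else np.zeros((0, len(keep_asvs)), int),
        keep_samples,
        keep_asvs,
    )


def filter_min_depth(table: AsvTable, min_reads: int) -> AsvTable:
    """Retain exactly the samples whose total read count is >= ``min_reads``."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    sums = table.row_sums()
    keep = [s for s, t in zip(table.sample_ids, sums) if t >= min_reads]
    return table.select_samples(keep)


def derive_seed(master_seed: int, label: str) -> int:
    """Derive a stage seed from a master seed by stable hashing of a label.

    Stable across runs and platforms (unlike ``hash``); result < 2**31.
    """
    digest = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def rarefy(table: AsvTable, depth: int, seed: int) -> AsvTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped.  Each sample's
    draw is a multivariate-hypergeometric subsample seeded by a stable
    hash of ``(seed, sample_id)``, so results do not depend on sample
    order.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    sums = table.row_sums()
    keep = [i for i, t in enumerate(sums) if t >= depth]
    rows = []
    ids = []
    for i in keep:
        sid = table.sample_ids[i]
        rng = np.random.default_rng(derive_seed(seed, f"rarefy:{sid}"))
        rows.append(rng.multivariate_hypergeometric(table.counts[i], depth))
        ids.append(sid)
    counts = np.asarray(rows, dtype=np.int64) if rows else np.zeros((0, table.n_asvs), int)
    return AsvTable(counts, ids, table.asv_ids)
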
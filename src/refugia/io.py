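"""Domain containers and text-format I/O shared by every pipeline stage.

All tabular formats are UTF-8, tab-delimited, with ``#``-prefixed comment
lines ignored.  Missing STR repeat counts are written as ``?`` and held
internally as NaN in a float array.  Distance matrices travel in the PHYLIP
square dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

__all__ = [
    "DEFAULT_LOCI",
    "PAPER_REGION_POOLING",
    "HaplotypeTable",
    "HaplogroupTree",
    "PopulationPooling",
    "DistanceMatrix",
    "GenotypeMatrix",
    "SchemaError",
    "read_haplotype_table",
    "write_haplotype_table",
    "read_pooling",
    "write_pooling",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_genotype_matrix",
    "write_genotype_matrix",
]

#: The 11 Y-STR loci shared by all source studies, in canonical column order.
DEFAULT_LOCI = (
    "DYS388", "DYS389I", "DYS390", "DYS391", "DYS393", "DYS19",
    "DYS437", "DYS439", "DYS389II", "DYS392", "DYS438",
)

#: Regional pooling of Southwest Asian / North African populations used for
#: the hierarchical (AMOVA) and split analyses.
PAPER_REGION_POOLING = {
    "Saudi Arabia": "Arabia",
    "Emirates": "Arabia",
    "Qatar": "Arabia",
    "Bahrain": "Arabia",
    "Yemen": "Yemen",
    "Armenia": "Armenia and Turkey",
    "Turkey": "Armenia and Turkey",
    "Georgia": "Caucasus",
    "Iran": "Mesopotamia",
    "Iraq": "Mesopotamia",
    "Kuwait": "Mesopotamia",
    "Cyprus": "Cyprus",
    "Jordan": "Southern Levant",
    "Palestine": "Southern Levant",
    "Lebanon": "Northern Levant",
    "Syria": "Northern Levant",
    "Egypt": "Egypt",
    "Libya": "North Africa",
    "Morocco": "North Africa",
    "Tunisia": "North Africa",
    "Algeria": "North Africa",
    "Ethiopia": "Ethiopia",
}

MISSING_CODE = "?"
_REPEAT_MIN, _REPEAT_MAX = 3, 60


class SchemaError(ValueError):
    """Raised when a file or container violates the declared schema."""


@dataclass
class HaplotypeTable:
    """Per-chromosome STR repeat counts plus population/haplogroup labels.

    Parameters
    ----------
    samples : pandas.DataFrame
        Columns ``sample_id``, ``population``, ``haplogroup`` and optionally
        ``region``.  Row order is meaningful and preserved on write.
    loci : tuple of str
        Ordered locus names; identical for every row.
    repeats : numpy.ndarray
        Float array of shape ``(n_samples, n_loci)``; NaN marks a missing
        call.  Observed values are integers in ``[3, 60]``.
    """

    samples: pd.DataFrame
    loci: tuple
    repeats: np.ndarray

    def __post_init__(self):
        self.loci = tuple(self.loci)
        self.repeats = np.asarray(self.repeats, dtype=float)
        self.validate()

    def validate(self):
        if self.repeats.shape != (len(self.samples), len(self.loci)):
            raise SchemaError(
                f"repeat matrix shape {self.repeats.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        ids = self.samples["sample_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise SchemaError(f"duplicate sample_id {dup!r}")
        obs = self.repeats[~np.isnan(self.repeats)]
        if obs.size:
            if not np.all(obs == np.round(obs)):
                raise SchemaError("non-integer repeat count present")
            if obs.min() < _REPEAT_MIN or obs.max() > _REPEAT_MAX:
                raise SchemaError(
                    f"repeat counts outside [{_REPEAT_MIN}, {_REPEAT_MAX}]"
                )

    def __len__(self):
        return len(self.samples)

    @property
    def populations(self):
        return self.samples["population"].to_numpy()

    @property
    def n_loci(self):
        return len(self.loci)

    def subset(self, mask) -> "HaplotypeTable":
        mask = np.asarray(mask)
        return HaplotypeTable(
            self.samples.iloc[mask].reset_index(drop=True)
            if mask.dtype.kind in "iu"
            else self.samples.loc[mask].reset_index(drop=True),
            self.loci,
            self.repeats[mask],
        )

    def relabel_populations(self, mapping: dict) -> "HaplotypeTable":
        """Return a copy with population labels replaced via ``mapping``
        (labels absent from the mapping are kept)."""
        samples = self.samples.copy()
        samples["population"] = samples["population"].map(
            lambda p: mapping.get(p, p)
        )
        return HaplotypeTable(samples, self.loci, self.repeats.copy())


@dataclass
class HaplogroupTree:
    """Rooted tree of haplogroup labels (YHRD-style nested clades).

    Internally a :class:`skbio.TreeNode`; every node carries a unique
    haplogroup label.  Optional UEP marker names may annotate edges through
    the ``uep`` mapping (child label -> marker name).
    """

    tree: skbio.TreeNode
    uep: dict = field(default_factory=dict)

    def __post_init__(self):
        labels = [n.name for n in self.tree.traverse() if n.name is not None]
        if len(labels) != len(set(labels)):
            raise SchemaError("duplicate haplogroup labels in tree")
        self._index = {n.name: n for n in self.tree.traverse()}

    @classmethod
    def from_newick(cls, text: str, uep: dict | None = None):
        return cls(skbio.TreeNode.read([text]), uep or {})

    def resolve(self, label: str) -> skbio.TreeNode:
        try:
            return self._index[label]
        except KeyError:
            raise SchemaError(f"unknown haplogroup label {label!r}") from None

    def ancestor_at_depth(self, label: str, depth: int) -> str:
        """Collapse ``label`` to its ancestor ``depth`` edges below the root
        (or itself if shallower)."""
        node = self.resolve(label)
        path = [node] + list(node.ancestors())  # leafward -> rootward
        path = path[::-1]  # root first
        return path[min(depth, len(path) - 1)].name


@dataclass
class PopulationPooling:
    """Mapping population -> region used to pool samples hierarchically."""

    mapping: dict

    def __post_init__(self):
        if not self.mapping:
            raise SchemaError("empty pooling")
        self.mapping = dict(self.mapping)

    @property
    def regions(self):
        seen = {}
        for region in self.mapping.values():
            seen.setdefault(region, None)
        return tuple(seen)

    def region_of(self, population: str) -> str:
        try:
            return self.mapping[population]
        except KeyError:
            raise SchemaError(f"population {population!r} not pooled") from None

    def populations_in(self, region: str):
        return tuple(p for p, r in self.mapping.items() if r == region)


class DistanceMatrix:
    """Symmetric non-negative matrix with zero diagonal over ordered labels.

    ``raw`` optionally retains signed estimates (e.g. negative R_ST) whose
    clamped-to-zero counterparts populate ``values``.
    """

    def __init__(self, labels, values, raw=None):
        self.labels = tuple(str(x) for x in labels)
        values = np.asarray(values, dtype=float)
        if values.shape != (len(self.labels), len(self.labels)):
            raise SchemaError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(values)):
            raise SchemaError("non-finite distances")
        if np.max(np.abs(values - values.T), initial=0.0) > 1e-12:
            raise SchemaError("matrix is not symmetric within 1e-12")
        if np.any(np.diag(values) != 0.0):
            raise SchemaError("diagonal must be exactly zero")
        if values.size and values.min() < 0:
            raise SchemaError("negative distances (store signed values in raw)")
        self.values = 0.5 * (values + values.T)
        np.fill_diagonal(self.values, 0.0)
        self.raw = None if raw is None else np.asarray(raw, dtype=float)

    def __len__(self):
        return len(self.labels)

    def __getitem__(self, pair):
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return self.values[i, j]

    def condensed(self):
        """Upper-triangle entries in scipy condensed order."""
        iu = np.triu_indices(len(self), k=1)
        return self.values[iu]

    def to_skbio(self) -> skbio.DistanceMatrix:
        return skbio.DistanceMatrix(self.values, ids=self.labels)


@dataclass
class GenotypeMatrix:
    """Biallelic SNP alternate-allele dosages, sites x samples.

    ``dosages`` is an int8 array with values in {0, 1, 2} and -1 for
    missing; ``populations`` labels each sample column.
    """

    site_ids: tuple
    sample_ids: tuple
    populations: tuple
    dosages: np.ndarray

    def __post_init__(self):
        self.site_ids = tuple(self.site_ids)
        self.sample_ids = tuple(self.sample_ids)
        self.populations = tuple(self.populations)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if len(set(self.site_ids)) != len(self.site_ids):
            raise SchemaError("duplicate site ids")
        if self.dosages.shape != (len(self.site_ids), len(self.sample_ids)):
            raise SchemaError("dosage shape mismatch")
        if len(self.populations) != len(self.sample_ids):
            raise SchemaError("population labels do not match samples")
        bad = ~np.isin(self.dosages, (-1, 0, 1, 2))
        if bad.any():
            raise SchemaError("dosages must be in {0,1,2} or -1 for missing")

    def samples_in(self, population: str):
        return [i for i, p in enumerate(self.populations) if p == population]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_META_COLS = ("sample_id", "population", "haplogroup")


def _read_lines(path):
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_haplotype_table(path, locus_spec=None) -> HaplotypeTable:
    """Read a tab-delimited haplotype table.

    Columns: ``sample_id  population  haplogroup  [region]  <locus...>``.
    ``locus_spec``, when given, fixes the expected locus names and order;
    otherwise the header defines them.
    """
    lines = list(_read_lines(path))
    if not lines:
        raise SchemaError(f"{path}: empty file (no header)")
    header = lines[0][1].split("\t")
    if header[:3] != list(_META_COLS):
        raise SchemaError(
            f"{path}: header must start with {' '.join(_META_COLS)}"
        )
    has_region = len(header) > 3 and header[3] == "region"
    n_meta = 4 if has_region else 3
    loci = tuple(header[n_meta:])
    if locus_spec is not None:
        locus_spec = tuple(locus_spec)
        if loci != locus_spec:
            raise SchemaError(
                f"{path}: loci {loci} do not match expected {locus_spec}"
            )
    if len(set(loci)) != len(loci):
        raise SchemaError(f"{path}: duplicate locus names in header")

    meta_rows, repeat_rows = [], []
    for lineno, line in lines[1:]:
        parts = line.split("\t")
        if len(parts) != n_meta + len(loci):
            raise SchemaError(
                f"{path}:{lineno}: expected {n_meta + len(loci)} fields, "
                f"got {len(parts)}"
            )
        meta_rows.append(parts[:n_meta])
        row = []
        for locus, tok in zip(loci, parts[n_meta:]):
            tok = tok.strip()
            if tok == MISSING_CODE or tok == "":
                row.append(np.nan)
            else:
                try:
                    row.append(float(int(tok)))
                except ValueError:
                    raise SchemaError(
                        f"{path}:{lineno}: non-integer repeat {tok!r} "
                        f"at locus {locus}"
                    ) from None
        repeat_rows.append(row)

    cols = list(_META_COLS) + (["region"] if has_region else [])
    samples = pd.DataFrame(meta_rows, columns=cols)
    repeats = (
        np.array(repeat_rows, dtype=float)
        if repeat_rows
        else np.empty((0, len(loci)))
    )
    return HaplotypeTable(samples, loci, repeats)


def write_haplotype_table(table: HaplotypeTable, path):
    cols = list(table.samples.columns)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols + list(table.loci)) + "\n")
        for i in range(len(table)):
            meta = [str(table.samples.iloc[i][c]) for c in cols]
            reps = [
                MISSING_CODE if np.isnan(v) else str(int(v))
                for v in table.repeats[i]
            ]
            fh.write("\t".join(meta + reps) + "\n")


def read_pooling(path) -> PopulationPooling:
    """Read a two-column ``population<TAB>region`` mapping file."""
    mapping = {}
    lines = list(_read_lines(path))
    if not lines:
        raise SchemaError(f"{path}: empty pooling file")
    start = 1 if lines[0][1].split("\t")[0] == "population" else 0
    for lineno, line in lines[start:]:
        parts = line.split("\t")
        if len(parts) != 2:
            raise SchemaError(f"{path}:{lineno}: expected 2 fields")
        pop, region = parts[0].strip(), parts[1].strip()
        if pop in mapping:
            raise SchemaError(f"{path}:{lineno}: population {pop!r} mapped twice")
        mapping[pop] = region
    return PopulationPooling(mapping)


def write_pooling(pooling: PopulationPooling, path):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("population\tregion\n")
        for pop, region in pooling.mapping.items():
            fh.write(f"{pop}\t{region}\n")


def write_distance_matrix(D: DistanceMatrix, path):
    """PHYLIP square format, 12 significant digits."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(D)}\n")
        for label, row in zip(D.labels, D.values):
            fh.write(label + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def read_distance_matrix(path) -> DistanceMatrix:
    lines = list(_read_lines(path))
    if not lines:
        raise SchemaError(f"{path}: empty distance file")
    n = int(lines[0][1].split()[0])
    if len(lines) - 1 != n:
        raise SchemaError(f"{path}: expected {n} rows, got {len(lines) - 1}")
    labels, rows = [], []
    for lineno, line in lines[1:]:
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != n + 1:
            raise SchemaError(f"{path}:{lineno}: expected {n + 1} fields")
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    return DistanceMatrix(labels, np.array(rows))


def write_genotype_matrix(geno: GenotypeMatrix, path):
    """SNP TSV: ``site_id`` column then one dosage column per sample; a
    ``#population`` comment row records sample populations."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#population\t" + "\t".join(geno.populations) + "\n")
        fh.write("site_id\t" + "\t".join(geno.sample_ids) + "\n")
        for sid, row in zip(geno.site_ids, geno.dosages):
            toks = [MISSING_CODE if v < 0 else str(int(v)) for v in row]
            fh.write(sid + "\t" + "\t".join(toks) + "\n")


def read_genotype_matrix(path) -> GenotypeMatrix:
    populations = None
    with open(path, encoding="utf-8") as fh:
        raw = fh.read().splitlines()
    body = []
    for line in raw:
        if line.startswith("#population\t"):
            populations = line.split("\t")[1:]
        elif line.strip() and not line.startswith("#"):
            body.append(line)
    if not body:
        raise SchemaError(f"{path}: empty genotype file")
    header = body[0].split("\t")
    sample_ids = header[1:]
    if populations is None:
        raise SchemaError(f"{path}: missing #population row")
    site_ids, rows = [], []
    for line in body[1:]:
        parts = line.split("\t")
        site_ids.append(parts[0])
        rows.append(
            [-1 if t == MISSING_CODE else int(t) for t in parts[1:]]
        )
    return GenotypeMatrix(
        site_ids, sample_ids, populations,
        np.array(rows, dtype=np.int8) if rows else np.empty((0, len(sample_ids)), dtype=np.int8),
    )
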
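"""Readers, writers and validated in-memory containers for all external formats.

The quantitative input is a MaxQuant-style reporter-intensity table: one row per
feature (phosphosite or protein), one intensity column per ``<run_id>.<channel_id>``
pair, plus optional annotation columns.  A reporter intensity of 0 or an empty cell
means "not quantified" and is stored as missing — downstream code never sees a zero
intensity as a number, which keeps log2 transforms and ratios well defined.

Interaction networks are read from STRING-style edge lists (either 0-1 or 0-999
combined-score scale, auto-detected per file), and gene sets from standard GMT.
Gene symbols are normalised to upper case throughout, because STRING and GMT
sources disagree on case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

PathLike = Union[str, Path]

#: columns recognised as feature annotation in reporter tables
DEFAULT_ANNOTATION_COLUMNS = (
    "protein_id",
    "gene_symbol",
    "site_position",
    "residue",
    "kind",
)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class MultiplexMatrix:
    """Raw reporter intensities for one quantification run.

    ``intensities`` is a features x channels DataFrame; NaN marks missing cells
    (unquantified reporter ions).  All non-missing intensities are positive.
    """

    run_id: str
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.intensities
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dups[:5]}")
        if df.columns.has_duplicates:
            raise FormatError("duplicate channel ids")
        vals = df.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) <= 0:
            raise FormatError("intensities must be > 0 or missing (0 encodes missing)")
        self.intensities = df.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def channel_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.intensities.isna()


@dataclass
class FeatureAnnotation:
    """Identity of one quantified feature (phosphosite or protein)."""

    feature_id: str
    protein_id: str = ""
    gene_symbol: str = ""
    site_position: Optional[int] = None
    residue: Optional[str] = None
    kind: str = "protein"

    def __post_init__(self) -> None:
        self.gene_symbol = self.gene_symbol.upper()
        if self.kind not in ("phosphosite", "protein"):
            raise FormatError(f"unknown feature kind {self.kind!r}")
        if self.kind == "phosphosite":
            if self.residue not in ("S", "T", "Y") or not self.site_position:
                raise FormatError(
                    f"phosphosite {self.feature_id} needs residue in S/T/Y and position >= 1"
                )
        else:
            if self.residue is not None or self.site_position is not None:
                raise FormatError(
                    f"protein feature {self.feature_id} must not carry residue/position"
                )


@dataclass
class SampleDesign:
    """Maps every (run, channel) to a sample and its condition / replicate labels."""

    table: pd.DataFrame  # run_id, channel_id, sample_id, condition, bio_rep, injection_rep

    REQUIRED = ("run_id", "channel_id", "sample_id", "condition", "bio_rep", "injection_rep")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise FormatError(f"design table lacks columns: {missing}")
        t = t.loc[:, list(self.REQUIRED)].copy()
        t["bio_rep"] = t["bio_rep"].astype(int)
        t["injection_rep"] = t["injection_rep"].astype(int)
        if t.duplicated(["run_id", "channel_id"]).any():
            bad = t[t.duplicated(["run_id", "channel_id"], keep=False)]
            raise FormatError(
                "duplicate (run_id, channel_id) assignments: "
                f"{bad[['run_id', 'channel_id']].drop_duplicates().values.tolist()}"
            )
        per_sample = t.groupby("sample_id")[["condition", "bio_rep"]].nunique()
        bad = per_sample[(per_sample > 1).any(axis=1)]
        if len(bad):
            raise FormatError(
                f"sample_id mapped to more than one (condition, bio_rep): {list(bad.index)}"
            )
        self.table = t.reset_index(drop=True)

    @property
    def conditions(self) -> list[str]:
        return list(pd.unique(self.table["condition"]))

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.table["sample_id"]))

    def samples_of(self, condition: str) -> list[str]:
        t = self.table
        return list(pd.unique(t.loc[t["condition"] == condition, "sample_id"]))

    def sample_to_condition(self) -> dict[str, str]:
        t = self.table.drop_duplicates("sample_id")
        return dict(zip(t["sample_id"], t["condition"]))

    def channels_for_run(self, run_id: str) -> pd.DataFrame:
        return self.table[self.table["run_id"] == run_id]


@dataclass
class EdgeList:
    """Undirected scored interactions; canonicalised (no self-loops, max-score dedup)."""

    table: pd.DataFrame  # node_a, node_b, combined_score

    def __post_init__(self) -> None:
        t = self.table.copy()
        for col in ("node_a", "node_b"):
            t[col] = t[col].astype(str).str.upper()
        t["combined_score"] = t["combined_score"].astype(float)
        if ((t["combined_score"] < 0) | (t["combined_score"] > 1)).any():
            raise FormatError("edge scores must lie in [0, 1] after scale normalisation")
        t = t[t["node_a"] != t["node_b"]]
        lo = t[["node_a", "node_b"]].min(axis=1)
        hi = t[["node_a", "node_b"]].max(axis=1)
        t = pd.DataFrame(
            {"node_a": lo, "node_b": hi, "combined_score": t["combined_score"].values}
        )
        t = (
            t.groupby(["node_a", "node_b"], as_index=False)["combined_score"]
            .max()
            .sort_values(["node_a", "node_b"])
            .reset_index(drop=True)
        )
        self.table = t

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GeneSetCollection:
    """Named gene sets; member symbols upper-cased and de-duplicated."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            seen: list[str] = []
            for m in members:
                mu = str(m).upper()
                if mu and mu not in seen:
                    seen.append(mu)
            if not seen:
                raise FormatError(f"gene set {name!r} is empty")
            clean[name] = seen
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# reporter tables
# ---------------------------------------------------------------------------


def _split_run_channel(col: str) -> tuple[str, str]:
    run, sep, chan = col.rpartition(".")
    if not sep or not run or not chan:
        raise FormatError(
            f"intensity column {col!r} is not named '<run_id>.<channel_id>'"
        )
    return run, chan


def read_reporter_table(
    path: PathLike,
    annotation_columns: Sequence[str] = DEFAULT_ANNOTATION_COLUMNS,
    feature_column: str = "feature_id",
) -> tuple[dict[str, MultiplexMatrix], list[FeatureAnnotation]]:
    """Read a multi-run reporter table into one MultiplexMatrix per run.

    Cells equal to 0 or empty are recorded as missing.  Raises FormatError on
    duplicate feature ids, non-numeric intensities (with coordinates) or columns
    that do not follow the ``<run_id>.<channel_id>`` naming rule.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if feature_column not in df.columns:
        raise FormatError(f"missing feature key column {feature_column!r}")
    df = df.set_index(feature_column)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate feature ids: {dups[:5]}")

    ann_cols = [c for c in annotation_columns if c in df.columns]
    intensity_cols = [c for c in df.columns if c not in ann_cols]
    if len(intensity_cols) < 2:
        raise FormatError("reporter table needs at least 2 intensity columns")

    runs: dict[str, list[str]] = {}
    for col in intensity_cols:
        run, _ = _split_run_channel(col)
        runs.setdefault(run, []).append(col)

    matrices: dict[str, MultiplexMatrix] = {}
    for run, cols in runs.items():
        block = df[cols]
        # exact strtod parsing (pandas' fast path is not round-trip precise);
        # blank cells are legal missing values, other non-numeric cells are errors
        def _parse(v):
            if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
                return np.nan
            return float(v)

        try:
            numeric = block.map(_parse)
        except ValueError:
            coerced = block.apply(pd.to_numeric, errors="coerce")
            blank = block.isna() | (block.astype(str).apply(lambda s: s.str.strip()) == "")
            r, c = np.argwhere((coerced.isna() & ~blank).values)[0]
            raise FormatError(
                f"non-numeric intensity {block.iloc[r, c]!r} at feature "
                f"{block.index[r]!r}, column {cols[c]!r}"
            ) from None
        numeric = numeric.mask(numeric == 0)  # MaxQuant zero == unquantified
        numeric.columns = [_split_run_channel(c)[1] for c in cols]
        matrices[run] = MultiplexMatrix(run_id=run, intensities=numeric)

    annotations: list[FeatureAnnotation] = []
    for fid, row in df[ann_cols].iterrows():
        kw: dict = {"feature_id": str(fid)}
        for c in ann_cols:
            v = row[c]
            if pd.isna(v) or str(v).strip() == "":
                continue
            if c == "site_position":
                kw[c] = int(float(v))
            else:
                kw[c] = str(v)
        annotations.append(FeatureAnnotation(**kw))
    return matrices, annotations


def write_reporter_table(
    path: PathLike,
    matrices: Mapping[str, MultiplexMatrix],
    annotations: Optional[Iterable[FeatureAnnotation]] = None,
    provenance: str = "combiphos reporter table",
) -> None:
    """Write runs back to the TSV dialect read_reporter_table consumes.

    Missing cells are written as 0, matching the MaxQuant convention.
    """
    frames = []
    for run_id, m in matrices.items():
        block = m.intensities.copy()
        block.columns = [f"{run_id}.{c}" for c in block.columns]
        frames.append(block)
    out = pd.concat(frames, axis=1)
    out.index.name = "feature_id"
    if annotations is not None:
        ann = pd.DataFrame(
            [
                {
                    "feature_id": a.feature_id,
                    "protein_id": a.protein_id,
                    "gene_symbol": a.gene_symbol,
                    "site_position": "" if a.site_position is None else a.site_position,
                    "residue": "" if a.residue is None else a.residue,
                    "kind": a.kind,
                }
                for a in annotations
            ]
        ).set_index("feature_id")
        out = ann.join(out, how="right")
        out.index.name = "feature_id"
    with open(path, "w") as fh:
        fh.write(f"# {provenance}\n")
        # %.17g guarantees bit-exact float round-trips through the text format
        out.fillna(0).to_csv(fh, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# design, edges, gene sets
# ---------------------------------------------------------------------------


def read_design(path: PathLike) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return SampleDesign(df)


def write_design(path: PathLike, design: SampleDesign, provenance: str = "combiphos design") -> None:
    with open(path, "w") as fh:
        fh.write(f"# {provenance}\n")
        design.table.to_csv(fh, sep="\t", index=False)


def check_design_coverage(
    design: SampleDesign, matrices: Mapping[str, MultiplexMatrix]
) -> list[str]:
    """Return human-readable warnings for design/matrix channel mismatches."""
    warnings: list[str] = []
    for run_id, m in matrices.items():
        declared = set(design.channels_for_run(run_id)["channel_id"])
        present = set(m.channel_ids)
        for ch in sorted(declared - present):
            warnings.append(f"design channel {run_id}.{ch} absent from matrix")
        for ch in sorted(present - declared):
            warnings.append(f"matrix channel {run_id}.{ch} not assigned in design")
    return warnings


def read_string_edges(path: PathLike, min_score: float = 0.15) -> EdgeList:
    """Read a STRING-style edge list, keeping edges with score >= min_score.

    Scores may be on the 0-1 or integer 0-999 scale; any value > 1 anywhere in
    the file switches interpretation of the whole file to the 0-999 scale.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"node_a", "node_b", "combined_score"}
    if not need.issubset(df.columns):
        raise FormatError(f"edge list needs columns {sorted(need)}")
    scores = df["combined_score"].astype(float)
    if (scores < 0).any() or (scores > 999).any():
        raise FormatError("edge scores must lie in [0, 999]")
    if (scores > 1).any():
        scores = scores / 1000.0
    df = df.assign(combined_score=scores)
    edges = EdgeList(df)
    kept = edges.table[edges.table["combined_score"] >= min_score].reset_index(drop=True)
    return EdgeList(kept)


def write_edges(path: PathLike, edges: EdgeList, provenance: str = "combiphos edges") -> None:
    with open(path, "w") as fh:
        fh.write(f"# {provenance}\n")
        edges.table.to_csv(fh, sep="\t", index=False)


def read_gmt(path: PathLike) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 fields")
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = [m for m in members if m]
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(path: PathLike, collection: GeneSetCollection) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def write_table(path: PathLike, df: pd.DataFrame, provenance: str, index: bool = False) -> None:
    """Write an output TSV with a one-line '#' provenance header."""
    with open(path, "w") as fh:
        fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep="\t", index=index)
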
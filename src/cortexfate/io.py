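"""Tabular I/O for panel count data, codesets, sample metadata and atlas profiles.

All artifacts are flat delimited text files:

* **count tables** — TSV, one row per sample, first column ``sample_id``,
  remaining columns named by probe;
* **codeset definitions** — TSV with columns ``probe_id``, ``gene_symbol``,
  ``probe_class`` and (for positive controls) ``pos_rank``;
* **sample metadata** — TSV keyed by ``sample_id``;
* **atlas expression energies** — CSV with one row per gene and one column
  per brain region, as exported from the Allen Developing Mouse Brain Atlas
  API (this module defines the file contract; it does not download).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PROBE_CLASSES = ("endogenous", "negative", "positive", "housekeeping")

#: Housekeeping genes of the study codesets; checked at codeset load time.
HOUSEKEEPING_GENES = frozenset(
    {"CLTC", "GAPDH", "GUSB", "PPIA", "RPLP1", "RPS15A", "RPS9"}
)

METADATA_COLUMNS = [
    "sample_id", "uin", "line", "individual", "genotype",
    "stage", "dpi", "treatment", "operator",
]


class FormatError(ValueError):
    """A file or in-memory table violates the documented contract."""


@dataclass
class CodesetDefinition:
    """Probe panel definition: probe ids, gene symbols and control classes."""

    codeset_id: str
    probes: pd.DataFrame  # columns: probe_id, gene_symbol, probe_class, pos_rank

    def __post_init__(self) -> None:
        required = {"probe_id", "gene_symbol", "probe_class"}
        if not required.issubset(self.probes.columns):
            raise FormatError(f"codeset table must have columns {sorted(required)}")
        if self.probes["probe_id"].duplicated().any():
            dup = self.probes.loc[self.probes["probe_id"].duplicated(), "probe_id"]
            raise FormatError(f"duplicate probe ids in codeset: {sorted(set(dup))}")
        bad = set(self.probes["probe_class"]) - set(PROBE_CLASSES)
        if bad:
            raise FormatError(f"unknown probe classes {sorted(bad)}")
        if "pos_rank" not in self.probes.columns:
            self.probes = self.probes.assign(pos_rank="")

    @property
    def probe_class(self) -> pd.Series:
        return self.probes.set_index("probe_id")["probe_class"]

    def class_counts(self) -> dict[str, int]:
        return self.probes["probe_class"].value_counts().to_dict()

    def probes_of_class(self, cls: str) -> list[str]:
        return list(self.probes.loc[self.probes["probe_class"] == cls, "probe_id"])

    def validate_control_design(
        self, n_negative: int = 8, n_positive: int = 6, n_housekeeping: int = 7
    ) -> None:
        """Check the control-probe design of the study codesets.

        The study panels carry 8 negative controls, 6 positive controls and
        the 7 housekeeping genes CLTC, GAPDH, GUSB, PPIA, RPLP1, RPS15A, RPS9.
        """
        counts = self.class_counts()
        got = (counts.get("negative", 0), counts.get("positive", 0),
               counts.get("housekeeping", 0))
        if got != (n_negative, n_positive, n_housekeeping):
            raise FormatError(
                f"codeset {self.codeset_id}: expected "
                f"{n_negative}/{n_positive}/{n_housekeeping} negative/positive/"
                f"housekeeping probes, found {got[0]}/{got[1]}/{got[2]}"
            )
        hk = set(
            self.probes.loc[self.probes["probe_class"] == "housekeeping",
                            "gene_symbol"]
        )
        if hk != set(HOUSEKEEPING_GENES):
            raise FormatError(
                f"codeset {self.codeset_id}: housekeeping genes {sorted(hk)} "
                f"!= expected {sorted(HOUSEKEEPING_GENES)}"
            )


@dataclass
class CountMatrix:
    """Raw integer probe counts, samples x probes, with probe classes."""

    counts: pd.DataFrame          # samples x probes, integer
    probe_class: pd.Series        # indexed by probe_id
    codeset_id: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            raise FormatError(
                f"duplicate sample ids: {sorted(set(c.index[c.index.duplicated()]))}"
            )
        if c.columns.duplicated().any():
            raise FormatError("duplicate probe ids in count matrix")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise FormatError("counts must be integral")
            self.counts = c.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise FormatError("counts must be non-negative")
        missing = set(c.columns) - set(self.probe_class.index)
        if missing:
            raise FormatError(f"probes without a class: {sorted(missing)}")
        self.probe_class = self.probe_class.loc[list(c.columns)]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.counts.columns)

    def probes_of_class(self, cls: str) -> list[str]:
        return list(self.probe_class.index[self.probe_class == cls])


@dataclass
class SampleMetadata:
    """Per-sample annotations: induction number, line, genotype, stage, dpi."""

    table: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        t = self.table
        if t.index.name != "sample_id":
            if "sample_id" in t.columns:
                t = t.set_index("sample_id")
            else:
                t.index.name = "sample_id"
        if t.index.duplicated().any():
            raise FormatError("duplicate sample ids in metadata")
        if "dpi" in t.columns:
            dpi = pd.to_numeric(t["dpi"], errors="coerce")
            if (dpi.dropna() < 0).any():
                raise FormatError("dpi must be >= 0")
            t = t.assign(dpi=dpi)
        self.table = t

    def require_samples(self, sample_ids: Iterable[str]) -> None:
        missing = set(sample_ids) - set(self.table.index)
        if missing:
            raise FormatError(f"samples without metadata: {sorted(missing)}")

    def column(self, name: str) -> pd.Series:
        return self.table[name]


@dataclass
class RegionalProfileSet:
    """Atlas expression-energy vectors, regions x genes."""

    energy: pd.DataFrame  # regions x genes, non-negative
    age_label: str = "E11.5"

    def __post_init__(self) -> None:
        if (self.energy.to_numpy() < 0).any():
            raise FormatError("expression energy must be non-negative")
        if self.energy.index.duplicated().any():
            raise FormatError("duplicate region ids")
        if self.energy.columns.duplicated().any():
            raise FormatError("duplicate gene ids")

    @property
    def region_ids(self) -> list[str]:
        return list(self.energy.index)

    @property
    def genes(self) -> list[str]:
        return list(self.energy.columns)

    def subset_regions(self, regions: Sequence[str]) -> "RegionalProfileSet":
        return RegionalProfileSet(self.energy.loc[list(regions)].copy(),
                                  self.age_label)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_codeset(path: str | Path, codeset_id: str | None = None) -> CodesetDefinition:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    cid = codeset_id or Path(path).stem
    return CodesetDefinition(codeset_id=cid, probes=df)


def write_codeset(codeset: CodesetDefinition, path: str | Path) -> None:
    codeset.probes.to_csv(path, sep="\t", index=False)


def read_count_table(path: str | Path, codeset: CodesetDefinition) -> CountMatrix:
    """Read a consolidated TSV count table and attach probe classes.

    Unknown probe columns raise; codeset probes missing from the file are
    reported (returned matrix simply lacks them). Malformed numeric cells
    raise a :class:`FormatError` naming the offending row and column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "sample_id":
        raise FormatError(f"{path}: first column must be 'sample_id'")
    if df["sample_id"].duplicated().any():
        dups = sorted(set(df.loc[df["sample_id"].duplicated(), "sample_id"]))
        raise FormatError(f"{path}: duplicate sample ids {dups}")
    df = df.set_index("sample_id")
    known = set(codeset.probes["probe_id"])
    unknown = [p for p in df.columns if p not in known]
    if unknown:
        raise FormatError(
            f"{path}: probes not in codeset {codeset.codeset_id}: {unknown}"
        )
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[vals.isna()][0]
            raise FormatError(
                f"{path}: malformed numeric cell at row '{row}', column '{col}'"
            )
        if (vals < 0).any():
            row = df.index[vals < 0][0]
            raise FormatError(
                f"{path}: negative count at row '{row}', column '{col}'"
            )
        out[col] = vals.astype(np.int64)
    return CountMatrix(counts=out, probe_class=codeset.probe_class,
                       codeset_id=codeset.codeset_id)


def write_count_table(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.rename_axis("sample_id").to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: metadata must have a sample_id column")
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.reset_index().to_csv(path, sep="\t", index=False)


def read_atlas_energy(path: str | Path, age_label: str = "E11.5") -> RegionalProfileSet:
    """Read a gene x region expression-energy CSV into a profile set.

    Duplicated gene rows with identical values are silently deduplicated;
    conflicting duplicates raise. Negative energies and empty region columns
    raise.
    """
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no region columns")
    for col in df.columns:
        if df[col].isna().all():
            raise FormatError(f"{path}: region column '{col}' is empty")
    if df.isna().any().any():
        raise FormatError(f"{path}: missing energy values")
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative expression energy")
    if df.index.duplicated().any():
        deduped = []
        for gene, grp in df.groupby(level=0, sort=False):
            uniq = grp.drop_duplicates()
            if len(uniq) > 1:
                raise FormatError(
                    f"{path}: gene '{gene}' duplicated with conflicting values"
                )
            deduped.append(uniq.iloc[[0]])
        df = pd.concat(deduped)
    energy = df.T
    energy.index.name = None
    energy.columns.name = None
    return RegionalProfileSet(energy=energy, age_label=age_label)


def write_atlas_energy(profiles: RegionalProfileSet, path: str | Path) -> None:
    profiles.energy.T.rename_axis("gene").to_csv(path)
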
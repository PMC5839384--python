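"""Readers and writers for the on-disk artifacts of the pipeline.

Formats are deliberately plain: tab-separated count matrices and sample
sheets, the standard GMT dialect for gene sets, CSV result tables and a YAML
run configuration.  All writers are deterministic for identical inputs (gene
rows keep input order, sample columns keep sample-sheet order), so outputs
diff bit-stably.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CountMatrix",
    "GeneSetCollection",
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gmt",
    "write_gmt",
    "read_config",
    "write_results",
]

DIETS = ("ecoli", "bsubtilis")
TEMPERATURES = (15, 20, 25)

_ID_RE = re.compile(r"^[A-Za-z0-9._-]+$")


@dataclass
class CountMatrix:
    """Gene x sample integer count matrix plus per-sample design factors.

    ``counts`` is a pandas DataFrame (index: gene ids, columns: sample ids,
    non-negative integers).  ``samples`` is a DataFrame indexed by sample id
    with columns ``diet`` (``ecoli``/``bsubtilis``), ``temperature``
    (15/20/25) and ``replicate``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = c.to_numpy()
        if arr.size:
            if not np.isfinite(arr).all():
                raise ValueError("counts must be finite")
            if (arr < 0).any():
                g, s = np.argwhere(arr < 0)[0]
                raise ValueError(
                    f"negative count at gene {c.index[g]!r}, sample {c.columns[s]!r}"
                )
            if not np.allclose(arr, np.round(arr)):
                g, s = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise ValueError(
                    f"non-integer count at gene {c.index[g]!r}, sample {c.columns[s]!r}"
                )
        self.counts = c.astype(np.int64)
        if self.samples is not None:
            _validate_sample_sheet(self.samples)
            missing = set(c.columns) - set(self.samples.index)
            if missing:
                raise ValueError(f"samples missing from sample sheet: {sorted(missing)[:5]}")
            # column order follows the sample sheet
            order = [s for s in self.samples.index if s in set(c.columns)]
            self.counts = self.counts.loc[:, order]
            self.samples = self.samples.loc[order]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def condition_groups(self) -> dict[tuple[str, int], list[str]]:
        """Sample ids per (diet, temperature) condition, in sheet order."""
        if self.samples is None:
            raise ValueError("no sample sheet attached")
        groups: dict[tuple[str, int], list[str]] = {}
        for sid, row in self.samples.iterrows():
            groups.setdefault((row["diet"], int(row["temperature"])), []).append(sid)
        return groups


def _validate_sample_sheet(samples: pd.DataFrame) -> None:
    for col in ("diet", "temperature", "replicate"):
        if col not in samples.columns:
            raise ValueError(f"sample sheet missing required column {col!r}")
    bad_diet = set(samples["diet"]) - set(DIETS)
    if bad_diet:
        raise ValueError(f"unknown diet value(s) {sorted(bad_diet)}; allowed: {DIETS}")
    bad_temp = set(int(t) for t in samples["temperature"]) - set(TEMPERATURES)
    if bad_temp:
        raise ValueError(
            f"temperature value(s) {sorted(bad_temp)} outside the physiological "
            f"vocabulary {TEMPERATURES}"
        )
    if samples.index.has_duplicates:
        raise ValueError("duplicate sample ids in sample sheet")


@dataclass
class GeneSetCollection:
    """Ordered mapping of term id -> (description, member gene ids)."""

    terms: dict[str, tuple[str, list[str]]]

    def __post_init__(self):
        for tid, (_, members) in self.terms.items():
            if not members:
                raise ValueError(f"empty term {tid!r} rejected")
            if len(set(members)) != len(members):
                raise ValueError(f"duplicate members in term {tid!r}")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.items())

    def members(self, term_id: str) -> list[str]:
        return self.terms[term_id][1]


def read_counts(path) -> CountMatrix:
    """Read a TSV count matrix (first column gene id, header of sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            vals = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as e:
            raise ValueError(f"non-numeric count in sample column {col!r}: {e}") from e
        neg = vals < 0
        if neg.any():
            raise ValueError(
                f"negative count at gene {df.index[neg.argmax()]!r}, sample {col!r}"
            )
        out[col] = vals
    return CountMatrix(counts=out)


def write_counts(matrix: CountMatrix, path) -> None:
    df = matrix.counts.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a TSV sample sheet: sample, diet, temperature, replicate."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "diet": str})
    if "sample" not in df.columns:
        raise ValueError("sample sheet must have a 'sample' column")
    df = df.set_index("sample")
    _validate_sample_sheet(df)
    df["temperature"] = df["temperature"].astype(int)
    df["replicate"] = df["replicate"].astype(int)
    return df


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    out = samples.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t", lineterminator="\n")


def read_gmt(path) -> GeneSetCollection:
    """Read the tab-separated GMT dialect: term, description, members..."""
    terms: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs term, description, >=1 member")
            tid, desc, members = fields[0], fields[1], fields[2:]
            members = [m for m in members if m]
            if tid in terms:
                raise ValueError(f"{path}:{lineno}: duplicate term id {tid!r}")
            terms[tid] = (desc, members)
    return GeneSetCollection(terms=terms)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for tid, (desc, members) in collection:
            fh.write("\t".join([tid, desc, *members]) + "\n")


_CONFIG_SCHEMA_VERSION = 1
_KNOWN_CONFIG_KEYS = {
    "schema_version",
    "counts",
    "sample_sheet",
    "gene_sets",
    "simulation",
    "alpha",
    "background_n",
    "min_term",
    "max_term",
    "outdir",
    "seed",
    "log_level",
}


def read_config(path) -> dict:
    """Read the YAML run configuration; unknown keys warn, never fail."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    unknown = set(cfg) - _KNOWN_CONFIG_KEYS
    if unknown:
        warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}", stacklevel=2)
    cfg.setdefault("schema_version", _CONFIG_SCHEMA_VERSION)
    return cfg


def write_results(tables: dict[str, pd.DataFrame], outdir, summary: dict | None = None) -> None:
    """Write one CSV per named table plus an optional JSON run summary.

    Floats are written with 12 significant digits so a read-back round-trip
    preserves them to that precision.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        if not _ID_RE.match(name.replace("/", "")):
            raise ValueError(f"table name {name!r} not filesystem-safe")
        df.to_csv(outdir / f"{name}.csv", float_format="%.12g", lineterminator="\n")
    if summary is not None:
        with open(outdir / "run_summary.json", "w", encoding="utf-8", newline="\n") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
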
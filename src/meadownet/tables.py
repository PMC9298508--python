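"""Count-table container and I/O: BIOM v1 (JSON) and TSV, rarefaction,
relative abundance, dominant-OTU filtering, domain merging and group subsetting.

The central object is :class:`CountTable`, a samples x OTUs integer matrix
tagged with the domain it was sequenced from (bacteria / fungi / archaea).
Merged multi-domain tables keep each OTU's origin recoverable through an id
prefix (``bac|``, ``fun|``, ``arc|``), so exported edge lists stay
self-describing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DOMAINS = ("bacteria", "fungi", "archaea")
DOMAIN_PREFIXES = {"bacteria": "bac|", "fungi": "fun|", "archaea": "arc|"}
_PREFIX_TO_DOMAIN = {v: k for k, v in DOMAIN_PREFIXES.items()}

SAMPLE_COLUMNS = ("disturbance", "surface", "block", "site")
ENV_COLUMNS = (
    "pH",
    "CON",
    "NH4N",
    "NO3N",
    "SOC",
    "TN",
    "total_coverage",
    "wet_weight",
    "dry_weight",
)


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


class EmptyGroupError(ValueError):
    """Raised when a sample selection matches no samples."""


@dataclass
class CountTable:
    """Samples x OTUs matrix of non-negative integer counts.

    Parameters
    ----------
    data
        DataFrame indexed by sample id, columns are OTU ids.
    domain
        One of ``bacteria``, ``fungi``, ``archaea`` or ``merged``.
    """

    data: pd.DataFrame
    domain: str = field(default="bacteria")

    def __post_init__(self):
        if self.domain not in DOMAINS and self.domain != "merged":
            raise ValidationError(f"unknown domain label: {self.domain!r}")
        if not self.data.index.is_unique:
            raise ValidationError("duplicate sample ids")
        if not self.data.columns.is_unique:
            raise ValidationError("duplicate OTU ids")
        arr = self.data.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("counts must be integers")
            self.data = self.data.astype(np.int64)
        if (self.data.to_numpy() < 0).any():
            bad = self.data.lt(0).any()
            raise ValidationError(
                f"negative counts in OTUs: {list(self.data.columns[bad])[:5]}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CountTable)
            and self.domain == other.domain
            and self.data.equals(other.data)
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_count_table(path, format: str = "tsv", domain: str = "bacteria") -> CountTable:
    """Read a count table from ``tsv`` (samples as rows) or ``biom-json``."""
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return CountTable(df, domain=domain)
    if format == "biom-json":
        return _read_biom_json(path)
    raise ValueError(f"unknown format: {format!r}")


def write_count_table(table: CountTable, path, format: str = "tsv") -> None:
    if format == "tsv":
        table.data.to_csv(path, sep="\t", index_label="sample_id")
    elif format == "biom-json":
        _write_biom_json(table, path)
    else:
        raise ValueError(f"unknown format: {format!r}")


def _write_biom_json(table: CountTable, path) -> None:
    # BIOM v1 stores observations (OTUs) as rows and samples as columns.
    mat = table.data.to_numpy().T
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "meadownet",
        "date": "",
        "rows": [{"id": o, "metadata": {"domain": table.domain}} for o in table.otu_ids],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "matrix_type": "dense",
        "matrix_element_type": "int",
        "shape": list(mat.shape),
        "data": mat.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def _read_biom_json(path) -> CountTable:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"malformed BIOM JSON at line {exc.lineno}: {exc.msg}")
    for key in ("rows", "columns", "shape", "data", "matrix_type"):
        if key not in doc:
            raise ValidationError(f"BIOM document missing key {key!r}")
    n_obs, n_samp = doc["shape"]
    if doc["matrix_type"] == "dense":
        mat = np.asarray(doc["data"])
    elif doc["matrix_type"] == "sparse":
        mat = np.zeros((n_obs, n_samp))
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        raise ValidationError(f"unknown matrix_type {doc['matrix_type']!r}")
    otus = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    domains = {
        (r.get("metadata") or {}).get("domain") for r in doc["rows"]
    } - {None}
    domain = domains.pop() if len(domains) == 1 else "merged"
    df = pd.DataFrame(mat.T, index=samples, columns=otus)
    return CountTable(df, domain=domain)


def read_sample_frame(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    missing = set(SAMPLE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"sample metadata missing columns: {sorted(missing)}")
    return frame


def write_sample_frame(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index_label="sample_id")


def read_env_table(path) -> pd.DataFrame:
    env = pd.read_csv(path, sep="\t", index_col=0)
    env.index = env.index.astype(str)
    return env


def write_env_table(env: pd.DataFrame, path) -> None:
    env.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def rarefy(table: CountTable, depth: int, seed) -> CountTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples whose total falls below ``depth`` are dropped with a logged
    warning. Retained row sums equal ``depth`` exactly; resampling is
    multivariate hypergeometric, i.e. draws without replacement.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.data.sum(axis=1)
    keep = totals >= depth
    dropped = list(table.data.index[~keep])
    if dropped:
        logger.warning(
            "rarefy: dropping %d sample(s) below depth %d: %s",
            len(dropped), depth, dropped,
        )
    rows = []
    for _, row in table.data.loc[keep].iterrows():
        counts = row.to_numpy()
        if counts.sum() == depth:
            rows.append(counts)
        else:
            rows.append(rng.multivariate_hypergeometric(counts, depth))
    data = pd.DataFrame(
        np.asarray(rows, dtype=np.int64) if rows else np.empty((0, table.shape[1]), int),
        index=table.data.index[keep],
        columns=table.data.columns,
    )
    return CountTable(data, domain=table.domain)


def relative_abundance(table: CountTable) -> pd.DataFrame:
    """Per-sample relative abundances; rows sum to 1."""
    totals = table.data.sum(axis=1)
    zero = totals == 0
    if zero.any():
        raise ValidationError(
            f"zero-sum samples: {list(table.data.index[zero])}"
        )
    return table.data.div(totals, axis=0)


def filter_dominant(table: CountTable, threshold: float = 1e-4) -> CountTable:
    """Keep OTUs whose mean relative abundance is strictly > ``threshold``.

    The default 1e-4 is the conventional 0.01 % dominance cut-off for
    co-occurrence network construction.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    mean_rel = relative_abundance(table).mean(axis=0)
    keep = mean_rel > threshold
    return CountTable(table.data.loc[:, keep], domain=table.domain)


def merge_domains(tables: list[CountTable]) -> CountTable:
    """Concatenate per-domain tables into one merged table.

    OTU ids get a domain prefix so cross-domain edges can be classified
    later. All tables must cover the same sample set.
    """
    if not tables:
        raise ValueError("no tables to merge")
    ref = set(tables[0].sample_ids)
    for t in tables[1:]:
        if set(t.sample_ids) != ref:
            diff = set(t.sample_ids) ^ ref
            raise ValidationError(f"sample sets differ; asymmetric difference: {sorted(diff)}")
    parts = []
    for t in tables:
        if t.domain == "merged":
            raise ValidationError("cannot merge an already-merged table")
        prefix = DOMAIN_PREFIXES[t.domain]
        part = t.data.loc[tables[0].sample_ids]
        part = part.rename(columns={c: prefix + c for c in part.columns})
        parts.append(part)
    merged = pd.concat(parts, axis=1)
    return CountTable(merged, domain="merged")


def domain_of_otu(otu_id: str) -> str:
    """Recover the source domain of a prefixed OTU id."""
    for prefix, domain in _PREFIX_TO_DOMAIN.items():
        if otu_id.startswith(prefix):
            return domain
    raise ValueError(f"OTU id {otu_id!r} carries no domain prefix")


def subset_by_group(
    table: CountTable,
    frame: pd.DataFrame,
    disturbance: str | None = None,
    surface: str | None = None,
) -> CountTable:
    """Restrict to samples matching the given disturbance and/or surface."""
    meta = frame.loc[frame.index.intersection(table.data.index)]
    mask = pd.Series(True, index=meta.index)
    if disturbance is not None:
        mask &= meta["disturbance"] == disturbance
    if surface is not None:
        mask &= meta["surface"] == surface
    ids = [s for s in table.sample_ids if s in set(meta.index[mask])]
    if not ids:
        raise EmptyGroupError(
            f"no samples with disturbance={disturbance!r}, surface={surface!r}"
        )
    return CountTable(table.data.loc[ids], domain=table.domain)
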
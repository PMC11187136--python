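"""16S taxonomic count tables: validation, filtering, rarefaction, matching.

The central container is :class:`CountTable`, an integer taxa x samples
matrix plus per-sample metadata (subject, role, body site, collection day,
collection time). Filtering follows the two-stage rule common in 16S
pipelines: drop shallow samples, then drop rare taxa by a prevalence /
abundance threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

ROLES = ("mother", "neonate")
SITES = ("buccal", "rectal", "vaginal", "stool")
META_COLUMNS = ("subject_id", "role", "site", "day", "collection_time")

PRENATAL = "prenatal"  # day marker for maternal pregnancy-visit samples


class CountTableError(ValueError):
    pass


class NonIntegerCountError(CountTableError):
    pass


class DuplicateIdError(CountTableError):
    pass


class MetadataMismatchError(CountTableError):
    pass


@dataclass
class CountTable:
    """Taxa x samples integer count matrix with sample metadata.

    ``counts`` has taxon ids as the index and sample ids as columns;
    ``meta`` is indexed by sample id and carries subject_id, role, site,
    day (0/1/2 as strings, or "prenatal") and collection_time.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        counts, meta = self.counts, self.meta
        if counts.index.duplicated().any():
            raise DuplicateIdError("duplicated taxon ids")
        if counts.columns.duplicated().any():
            raise DuplicateIdError("duplicated sample ids")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise NonIntegerCountError("counts must be numeric integers")
        if np.isnan(arr.astype(float)).any():
            raise NonIntegerCountError("counts contain missing values")
        if (arr.astype(float) % 1 != 0).any():
            raise NonIntegerCountError("counts contain non-integer values")
        if (arr < 0).any():
            raise CountTableError("counts contain negative values")
        if not np.issubdtype(arr.dtype, np.integer):
            self.counts = counts.astype(np.int64)
        if set(meta.index) != set(counts.columns) or len(meta) != counts.shape[1]:
            raise MetadataMismatchError(
                "metadata rows do not match sample columns exactly"
            )
        missing_cols = set(META_COLUMNS) - set(meta.columns)
        if missing_cols:
            raise MetadataMismatchError(f"metadata missing columns: {sorted(missing_cols)}")
        # keep metadata in sample-column order
        self.meta = meta.loc[list(counts.columns)]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids) -> "CountTable":
        sample_ids = list(sample_ids)
        return CountTable(self.counts[sample_ids].copy(), self.meta.loc[sample_ids].copy())


# -- I/O -------------------------------------------------------------------


def load_counts(counts_path, meta_path) -> CountTable:
    """Read a tab-separated taxa x samples matrix plus its metadata file."""
    raw = pd.read_csv(counts_path, sep="\t", index_col=0)
    arr = raw.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or (arr.astype(float) % 1 != 0).any():
        raise NonIntegerCountError(f"non-integer count in {counts_path}")
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id", dtype={"day": str})
    raw.index.name = None
    meta.index.name = None
    return CountTable(raw.astype(np.int64), meta)


def write_counts(table: CountTable, counts_path, meta_path) -> None:
    table.counts.to_csv(counts_path, sep="\t", index_label="taxon_id")
    table.meta.to_csv(meta_path, sep="\t", index_label="sample_id")


# -- Filtering -------------------------------------------------------------


def filter_samples(table: CountTable, min_reads: int = 5000) -> CountTable:
    """Keep samples with at least ``min_reads`` total reads (inclusive)."""
    keep = table.totals() >= min_reads
    if not keep.any():
        warnings.warn("filter_samples removed every sample", stacklevel=2)
    kept = [s for s in table.sample_ids if keep[s]]
    return CountTable(table.counts[kept], table.meta.loc[kept])


def filter_taxa(
    table: CountTable,
    abundance_threshold: float = 0.001,
    abundance_prevalence: float = 0.05,
    presence_prevalence: float = 0.15,
) -> CountTable:
    """Keep a taxon iff its relative abundance exceeds 0.1% in more than 5%
    of samples, or it has >= 1 read in more than 15% of samples. Both
    prevalence comparisons are strict."""
    totals = table.totals().to_numpy(dtype=float)
    if (totals == 0).any():
        raise CountTableError("zero-total sample; filter samples first")
    rel = table.counts.to_numpy(dtype=float) / totals
    n = table.n_samples
    frac_abundant = (rel > abundance_threshold).sum(axis=1) / n
    frac_present = (table.counts.to_numpy() >= 1).sum(axis=1) / n
    keep = (frac_abundant > abundance_prevalence) | (frac_present > presence_prevalence)
    return CountTable(table.counts.loc[keep], table.meta)


def rarefy(table: CountTable, depth: int = 5000, seed: int = 0) -> CountTable:
    """Subsample each sample to exactly ``depth`` reads without replacement
    (multivariate hypergeometric draw), deterministically under ``seed``."""
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.to_numpy())
    totals = table.totals()
    for j, s in enumerate(table.sample_ids):
        col = table.counts[s].to_numpy()
        if totals[s] < depth:
            raise CountTableError(
                f"sample {s!r} has {totals[s]} reads, below rarefaction depth {depth}"
            )
        if totals[s] == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    counts = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return CountTable(counts, table.meta)


def relative_abundance(table: CountTable) -> pd.DataFrame:
    """Proportions per sample; columns sum to 1."""
    totals = table.totals()
    if (totals == 0).any():
        zero = list(totals[totals == 0].index)
        raise CountTableError(f"zero-total samples: {zero}")
    return table.counts / totals


# -- Dyad sample matching --------------------------------------------------


def match_dyad_samples(table: CountTable, site: str | None = None) -> CountTable:
    """Select one sample per dyad per analysis slot.

    Slots: the maternal sample is the *last* pregnancy visit; the neonatal
    day-0 sample is the *first* day-0 visit; the "day 1 or 2" sample is the
    first day-1 sample, falling back to the first day-2 sample when no
    day-1 sample exists. Collection-time ties break by sample id. Dyads
    lacking a slot simply have no sample labelled for it. The returned
    table's metadata gains a ``slot`` column
    (maternal / day0 / day1or2).
    """
    meta = table.meta
    if site is not None:
        meta = meta[meta["site"] == site]
    chosen: list[tuple[str, str]] = []
    for _subject, sub in meta.groupby("subject_id", sort=True):
        sub = sub.assign(_sid=sub.index).sort_values(["collection_time", "_sid"])
        maternal = sub[(sub["role"] == "mother") & (sub["day"].astype(str) == PRENATAL)]
        if len(maternal):
            chosen.append((maternal.index[-1], "maternal"))
        neo = sub[sub["role"] == "neonate"]
        day0 = neo[neo["day"].astype(str) == "0"]
        if len(day0):
            chosen.append((day0.index[0], "day0"))
        day1 = neo[neo["day"].astype(str) == "1"]
        day2 = neo[neo["day"].astype(str) == "2"]
        if len(day1):
            chosen.append((day1.index[0], "day1or2"))
        elif len(day2):
            chosen.append((day2.index[0], "day1or2"))
    if not chosen:
        warnings.warn("no samples matched any dyad slot", stacklevel=2)
    ids = [s for s, _ in chosen]
    out = table.subset_samples(ids)
    out.meta = out.meta.copy()
    out.meta["slot"] = [slot for _, slot in chosen]
    return out


# -- Cohort summaries ------------------------------------------------------


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, matching hand-tabulated percentages."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def cohort_summary(categories, denominator: int | None = None) -> pd.DataFrame:
    """Per-level counts and one-decimal percentages.

    ``categories`` is either a Series of per-dyad category labels or a
    mapping level -> count. The percentage denominator defaults to the
    number of dyads (sum of counts).
    """
    if isinstance(categories, pd.Series):
        counts = categories.value_counts().sort_index()
    else:
        counts = pd.Series(dict(categories)).sort_index()
    if denominator is None:
        denominator = int(counts.sum())
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = counts.map(lambda c: round_half_up(100.0 * c / denominator, 1))
    return pd.DataFrame({"count": counts.astype(int), "percent": pct})
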
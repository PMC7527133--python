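"""OTU count tables: the container, normalization, and the filter sweep.

The :class:`OtuTable` is the currency of the whole pipeline: an integer count
matrix (samples x OTUs) together with a 7-rank taxonomy per OTU and per-sample
metadata (date, lake-cycle phase label, dataset tag ``TS`` for the lake time
series or ``MC`` for the dilution mixed cultures).

Counts are compositional: each sample is rarefied to an even sequencing depth
(1,500 reads for the time series, 500 for the cultures) before any correlation
analysis, so only relative information is retained.  Filtering of rare OTUs is
done by a grid sweep over (detection frequency, total relative abundance)
criteria, scored against the two standard network-readiness recommendations:
table sparsity at most 50% and mean effective diversity (inverse Simpson
n_eff) at least 10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("cohortnet")

#: The seven taxonomic ranks carried by every OTU, coarsest first.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: The six lake-cycle phase labels (three seasons; summer split into the
#: three stratified layers).
PHASES = ("spring", "autumn", "winter", "epilimnion", "metalimnion", "hypolimnion")


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class EmptyTableError(ValueError):
    """An operation received (or would produce) a table with no usable data."""


@dataclass
class OtuTable:
    """Integer OTU count matrix with taxonomy and sample metadata.

    Parameters
    ----------
    counts
        Samples x OTUs integer DataFrame; index = sample ids, columns = OTU
        ids.  Non-negative integers.
    taxonomy
        OTUs x 7 ranks DataFrame (columns :data:`RANKS`), indexed like
        ``counts.columns``.
    sample_meta
        Per-sample DataFrame indexed like ``counts.index``; conventional
        columns are ``date``, ``phase`` and ``dataset`` (``TS``/``MC``).
        Mixed-culture tables additionally carry a boolean ``detected``.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        cnt = self.counts
        if (cnt.to_numpy() < 0).any():
            raise InvalidArgumentError("counts must be non-negative")
        if not np.issubdtype(cnt.to_numpy().dtype, np.integer):
            arr = cnt.to_numpy()
            if not np.allclose(arr, np.round(arr)):
                raise InvalidArgumentError("counts must be integral")
            self.counts = cnt.astype(np.int64)
        if list(self.taxonomy.index) != list(cnt.columns):
            self.taxonomy = self.taxonomy.loc[cnt.columns]
        missing = [r for r in RANKS if r not in self.taxonomy.columns]
        if missing:
            raise InvalidArgumentError(f"taxonomy lacks ranks: {missing}")
        if list(self.sample_meta.index) != list(cnt.index):
            self.sample_meta = self.sample_meta.loc[cnt.index]

    # -- derived quantities -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    @property
    def proportions(self) -> pd.DataFrame:
        """Per-sample relative abundances; rows with reads sum to 1."""
        tot = self.counts.sum(axis=1).to_numpy().astype(float)
        tot[tot == 0] = np.nan
        return self.counts.div(tot, axis=0)

    @property
    def av_ra(self) -> pd.Series:
        """Average relative abundance (av.ra) of each OTU over samples."""
        return self.proportions.mean(axis=0, skipna=True)

    @property
    def prevalence(self) -> pd.Series:
        """Fraction of samples in which each OTU is detected (count > 0)."""
        return (self.counts > 0).mean(axis=0)

    # -- subsetting ---------------------------------------------------------

    def select_otus(self, otus) -> "OtuTable":
        otus = list(otus)
        return OtuTable(self.counts[otus].copy(), self.taxonomy.loc[otus].copy(),
                        self.sample_meta.copy())

    def select_samples(self, samples) -> "OtuTable":
        samples = list(samples)
        return OtuTable(self.counts.loc[samples].copy(), self.taxonomy.copy(),
                        self.sample_meta.loc[samples].copy())

    # -- I/O: the TSV dialect (rows = OTUs, cols = samples + 7 rank cols) ---

    def to_tsv(self, path) -> None:
        out = self.counts.T.copy()
        for rank in RANKS:
            out[rank] = self.taxonomy[rank]
        out.index.name = "otu_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, sample_meta: pd.DataFrame | None = None) -> "OtuTable":
        raw = pd.read_csv(path, sep="\t", index_col=0)
        raw.index.name = None
        tax = raw[list(RANKS)]
        counts = raw.drop(columns=list(RANKS)).T.astype(np.int64)
        counts.columns.name = None
        if sample_meta is None:
            sample_meta = pd.DataFrame(index=counts.index)
        return cls(counts, tax, sample_meta)


@dataclass
class TableSummary:
    """Network-readiness summary of an OTU table."""

    sparsity: float
    n_eff: pd.Series          # per-sample inverse Simpson; NaN for empty samples
    n_eff_min: float
    n_eff_mean: float
    n_eff_max: float
    n_empty_samples: int = 0


@dataclass
class FilterCriteria:
    """A rare-OTU filter: minimum detection frequency and total abundance.

    ``min_total_ra`` thresholds the OTU's summed per-sample proportions when
    ``total_ra_mode == "sum"`` (the default reading of "total relative
    abundance"), or its mean per-sample proportion when ``"mean"``.  With
    ``strict=True`` both comparisons are strict (``>``) instead of ``>=``.
    """

    min_samples: int = 0
    min_total_ra: float = 0.0
    total_ra_mode: str = "sum"
    strict: bool = False

    def __post_init__(self) -> None:
        if self.min_samples < 0 or self.min_total_ra < 0:
            raise InvalidArgumentError("filter criteria must be non-negative")
        if self.total_ra_mode not in ("sum", "mean"):
            raise InvalidArgumentError("total_ra_mode must be 'sum' or 'mean'")


def ts_filter_preset() -> FilterCriteria:
    """The time-series filter: detected in >= 29 samples, mean ra >= 0.1%."""
    return FilterCriteria(min_samples=29, min_total_ra=0.001, total_ra_mode="mean")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to an even depth, without replacement.

    Samples with fewer than ``depth`` total reads are dropped (and logged),
    not up-sampled.  Uses exact multivariate hypergeometric sampling, so a
    sample whose total equals ``depth`` is returned unchanged.
    """
    if depth < 1:
        raise InvalidArgumentError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=1)
    keep = totals[totals >= depth].index
    dropped = [s for s in table.counts.index if s not in set(keep)]
    if dropped:
        logger.info("rarefy: dropping %d samples below depth %d: %s",
                    len(dropped), depth, dropped)
    if len(keep) == 0:
        raise EmptyTableError(f"no sample reaches rarefaction depth {depth}")
    rows = []
    for s in keep:
        row = table.counts.loc[s].to_numpy()
        rows.append(rng.multivariate_hypergeometric(row, depth))
    counts = pd.DataFrame(np.asarray(rows, dtype=np.int64),
                          index=keep, columns=table.counts.columns)
    return OtuTable(counts, table.taxonomy.copy(), table.sample_meta.loc[keep].copy())


def summarize(table: OtuTable) -> TableSummary:
    """Sparsity and per-sample inverse-Simpson effective diversity (n_eff).

    ``n_eff = 1 / sum_i p_i^2`` over the sample's proportions; a sample with
    zero total reads has undefined n_eff and is excluded from the summary
    statistics (counted in ``n_empty_samples``).
    """
    if table.n_samples == 0:
        raise EmptyTableError("cannot summarize a table with no samples")
    arr = table.counts.to_numpy().astype(float)
    sparsity = float((arr == 0).mean())
    tot = arr.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = arr / tot[:, None]
        n_eff = 1.0 / (p ** 2).sum(axis=1)
    n_eff = pd.Series(np.where(tot > 0, n_eff, np.nan), index=table.counts.index,
                      name="n_eff")
    valid = n_eff.dropna()
    if valid.empty:
        raise EmptyTableError("all samples are empty; n_eff undefined")
    return TableSummary(
        sparsity=sparsity,
        n_eff=n_eff,
        n_eff_min=float(valid.min()),
        n_eff_mean=float(valid.mean()),
        n_eff_max=float(valid.max()),
        n_empty_samples=int(n_eff.isna().sum()),
    )


def apply_filter(table: OtuTable, criteria: FilterCriteria) -> OtuTable:
    """Keep OTUs meeting both the detection-frequency and total-ra criteria."""
    detected = (table.counts > 0).sum(axis=0)
    total_ra = table.proportions.sum(axis=0, skipna=True)
    if criteria.total_ra_mode == "mean":
        total_ra = table.proportions.mean(axis=0, skipna=True)
    if criteria.strict:
        keep = (detected > criteria.min_samples) & (total_ra > criteria.min_total_ra)
    else:
        keep = (detected >= criteria.min_samples) & (total_ra >= criteria.min_total_ra)
    return table.select_otus(table.counts.columns[keep])


@dataclass
class SweepResult:
    """Outcome of :func:`filter_sweep`: chosen criteria, table, and the grid."""

    criteria: FilterCriteria
    table: OtuTable
    grid: pd.DataFrame           # one row per grid point with summary columns
    passed: bool                 # did any grid point satisfy both targets?


def filter_sweep(
    table: OtuTable,
    min_samples_grid,
    min_total_ra_grid,
    max_sparsity: float = 0.5,
    min_mean_neff: float = 10.0,
    total_ra_mode: str = "sum",
) -> SweepResult:
    """Sweep filter criteria and pick the best network-ready table.

    Every grid point is applied and summarized.  Among points whose filtered
    table satisfies ``sparsity <= max_sparsity`` and ``mean n_eff >=
    min_mean_neff``, the one retaining the most OTUs wins (ties broken by
    lower ``min_samples``, then lower ``min_total_ra``).  If no point
    qualifies the lowest-sparsity point is returned with ``passed=False``.
    """
    min_samples_grid = list(min_samples_grid)
    min_total_ra_grid = list(min_total_ra_grid)
    if not min_samples_grid or not min_total_ra_grid:
        raise InvalidArgumentError("sweep grids must be non-empty")
    if table.n_otus == 0 or table.n_samples == 0:
        raise EmptyTableError("cannot sweep an empty table")
    records = []
    tables = {}
    for ms in min_samples_grid:
        for ra in min_total_ra_grid:
            crit = FilterCriteria(ms, ra, total_ra_mode=total_ra_mode)
            sub = apply_filter(table, crit)
            if sub.n_otus == 0:
                records.append(dict(min_samples=ms, min_total_ra=ra, n_otus=0,
                                    sparsity=np.nan, n_eff_mean=np.nan, ok=False))
                continue
            summ = summarize(sub)
            ok = summ.sparsity <= max_sparsity and summ.n_eff_mean >= min_mean_neff
            records.append(dict(min_samples=ms, min_total_ra=ra, n_otus=sub.n_otus,
                                sparsity=summ.sparsity, n_eff_mean=summ.n_eff_mean,
                                ok=ok))
            tables[(ms, ra)] = sub
    grid = pd.DataFrame.from_records(records)
    qualifying = grid[grid["ok"]]
    if not qualifying.empty:
        best = qualifying.sort_values(
            ["n_otus", "min_samples", "min_total_ra"],
            ascending=[False, True, True]).iloc[0]
        passed = True
    else:
        logger.warning("filter_sweep: no grid point meets sparsity<=%.2f and "
                       "mean n_eff>=%.1f; falling back to lowest sparsity",
                       max_sparsity, min_mean_neff)
        nonempty = grid[grid["n_otus"] > 0]
        if nonempty.empty:
            raise EmptyTableError("every grid point empties the table")
        best = nonempty.sort_values("sparsity").iloc[0]
        passed = False
    crit = FilterCriteria(int(best["min_samples"]), float(best["min_total_ra"]),
                          total_ra_mode=total_ra_mode)
    return SweepResult(crit, tables[(crit.min_samples, crit.min_total_ra)],
                       grid, passed)


def drop_singletons(table: OtuTable) -> OtuTable:
    """Remove OTUs whose total count over all samples is <= 1."""
    keep = table.counts.sum(axis=0) > 1
    return table.select_otus(table.counts.columns[keep])


def collapse_rank(table: OtuTable, rank: str) -> pd.DataFrame:
    """Sum counts over OTUs sharing a label at ``rank``; returns proportions.

    ``rank`` may be any of the 7 ranks or ``"otu"`` (identity).  The result is
    a samples x clades DataFrame of relative abundances.
    """
    if rank == "otu":
        return table.proportions
    if rank not in RANKS:
        raise InvalidArgumentError(f"unknown rank {rank!r}; expected one of "
                                   f"{RANKS + ('otu',)}")
    grouped = table.counts.T.groupby(table.taxonomy[rank]).sum().T
    tot = grouped.sum(axis=1).to_numpy().astype(float)
    tot[tot == 0] = np.nan
    return grouped.div(tot, axis=0)


def collapse_rank_counts(table: OtuTable, rank: str) -> pd.DataFrame:
    """Like :func:`collapse_rank` but returning summed counts, not proportions."""
    if rank == "otu":
        return table.counts
    if rank not in RANKS:
        raise InvalidArgumentError(f"unknown rank {rank!r}")
    return table.counts.T.groupby(table.taxonomy[rank]).sum().T
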
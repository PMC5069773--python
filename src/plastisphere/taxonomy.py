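"""Lowest-common-ancestor taxonomic profiling of SSU rRNA shotgun reads.

Shotgun reads mapping to small-subunit rRNA reference sequences carry
many near-tied database hits, so assigning each read to its single best
hit over-resolves the taxonomy.  Instead, for every read:

1. hits are screened against a curated reference (flagged chimeric
   subjects and masked contaminant coordinate ranges are dropped),
2. hits passing an alignment-length floor (100 bp) and a bit-score
   floor (50) whose bit score lies within 1% of the best qualifying
   hit's score are retained, and
3. the read is assigned to the lowest common ancestor (LCA) of the
   retained subjects' lineages — e.g. two retained hits in the same
   family but different genera yield a family-level assignment.

Per-clade read counts are converted to proportions under an explicit
denominator and rounded to a fixed decimal resolution, which equalizes
effective depth across libraries much like rarefying to ~10^decimals
reads but without resampling noise.  Downstream helpers provide
square-root Bray-Curtis NMDS ordination, thresholded family richness
with Welch's t-test, and per-clade Mann-Whitney group tests with
Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist
from sklearn.base import BaseEstimator
from sklearn.manifold import MDS

from .stats import bh_adjust, mannwhitney_table

__all__ = [
    "RANKS",
    "Taxonomy",
    "ReadAssignment",
    "AbundanceTable",
    "LCATaxonomyClassifier",
    "read_hit_table",
    "retain_hits",
    "blacklist_filter",
    "lca_assign",
    "assign_reads",
    "clade_table",
    "round_normalize",
    "round_half_away",
    "sqrt_bray_nmds",
    "family_richness",
    "clade_group_test",
    "mean_top_identity",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus")

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass
class Taxonomy:
    """Reference lineages plus curation metadata.

    ``lineages`` maps subject accession to an ordered rank path
    (domain → genus, possibly truncated).  ``blacklist`` holds accessions
    that must never receive assignments; ``masks`` maps accessions to
    1-based inclusive coordinate intervals flagged as contaminant
    (non-SSU) sequence — hits overlapping any masked interval are
    discarded.
    """

    lineages: dict
    blacklist: set = field(default_factory=set)
    masks: dict = field(default_factory=dict)

    def __post_init__(self):
        for acc, lin in self.lineages.items():
            lin = tuple(lin)
            if not lin:
                raise ValueError(f"empty lineage for {acc}")
            self.lineages[acc] = lin

    def lineage(self, accession: str) -> tuple:
        return self.lineages[accession]

    @classmethod
    def from_tsv(cls, path, blacklist_path=None, mask_path=None) -> "Taxonomy":
        """Load accession → 'domain;phylum;...' lineage TSV plus optional
        blacklist (one accession per line) and mask (accession, start, end) TSVs."""
        df = pd.read_csv(path, sep="\t", header=None, names=["accession", "lineage"],
                         comment="#", dtype=str)
        lineages = {
            row.accession: tuple(t.strip() for t in row.lineage.split(";") if t.strip())
            for row in df.itertuples()
        }
        blacklist = set()
        if blacklist_path is not None:
            bl = pd.read_csv(blacklist_path, sep="\t", header=None, comment="#", dtype=str)
            blacklist = set(bl[0])
        masks: dict = {}
        if mask_path is not None:
            mk = pd.read_csv(mask_path, sep="\t", header=None, comment="#",
                             names=["accession", "start", "end"],
                             dtype={"accession": str})
            for row in mk.itertuples():
                masks.setdefault(row.accession, []).append((int(row.start), int(row.end)))
        return cls(lineages=lineages, blacklist=blacklist, masks=masks)

    def to_tsv(self, path):
        with open(path, "w") as fh:
            for acc, lin in self.lineages.items():
                fh.write(f"{acc}\t{';'.join(lin)}\n")


@dataclass
class ReadAssignment:
    read_id: str
    lineage: tuple
    rank_achieved: str  # deepest rank name, or "root" if unassignable
    top_pident: float

    @property
    def depth(self) -> int:
        return len(self.lineage)


@dataclass
class AbundanceTable:
    """Clade × sample counts at a fixed rank, with denominator metadata.

    ``counts`` is indexed by clade with one column per sample;
    ``denominators`` records the per-sample denominator implied by
    ``denominator_mode``; ``normalized`` holds rounded proportions once
    :func:`round_normalize` has been applied (``decimals`` records the
    resolution).
    """

    counts: pd.DataFrame
    denominators: pd.Series
    rank: str
    denominator_mode: str
    decimals: int | None = None
    normalized: pd.DataFrame | None = None

    @property
    def proportions(self) -> pd.DataFrame:
        return self.counts.div(self.denominators, axis=1).fillna(0.0)

    def values_for_tests(self) -> pd.DataFrame:
        return self.normalized if self.normalized is not None else self.proportions

    @property
    def samples(self):
        return list(self.counts.columns)


def read_hit_table(path) -> pd.DataFrame:
    """Read a BLAST/LAST tabular (outfmt-6-like) hit file.

    Accepts a headered TSV or the standard 12-column headerless format;
    tolerates missing optional columns.  Required: qseqid, sseqid,
    pident, length, bitscore.  Hit tables are assumed pre-filtered at
    the aligner's E-value cutoff.
    """
    peek = pd.read_csv(path, sep="\t", nrows=1, header=None, dtype=str)
    has_header = "qseqid" in peek.iloc[0].values
    if has_header:
        df = pd.read_csv(path, sep="\t")
    else:
        ncol = peek.shape[1]
        df = pd.read_csv(path, sep="\t", header=None, names=OUTFMT6_COLUMNS[:ncol])
    missing = {"qseqid", "sseqid", "pident", "length", "bitscore"} - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing required columns: {sorted(missing)}")
    return df


def retain_hits(hits: pd.DataFrame, min_len: int = 100, min_bit: float = 50.0,
                window: float = 0.01) -> pd.DataFrame:
    """Hit retention rule for one read.

    Keeps hits with alignment length >= ``min_len`` bp and bit score >=
    ``min_bit`` whose bit score is within ``window`` (fractionally) of
    the best floor-qualifying hit, the best hit included.  The result is
    independent of input order; an empty input (or none qualifying)
    returns an empty frame and the read goes unassigned.
    """
    if len(hits) == 0:
        return hits
    if hits["qseqid"].nunique() > 1:
        raise ValueError("retain_hits expects hits for a single read")
    qualifying = hits[(hits["length"] >= min_len) & (hits["bitscore"] >= min_bit)]
    if len(qualifying) == 0:
        return qualifying
    best = qualifying["bitscore"].max()
    return qualifying[qualifying["bitscore"] >= (1.0 - window) * best]


def _intervals_overlap(a_start, a_end, b_start, b_end) -> bool:
    # 1-based inclusive coordinates; reversed (minus-strand) hits normalized
    lo, hi = min(a_start, a_end), max(a_start, a_end)
    return max(lo, b_start) <= min(hi, b_end)


def blacklist_filter(hits: pd.DataFrame, taxonomy: Taxonomy) -> pd.DataFrame:
    """Drop hits to blacklisted subjects or overlapping masked intervals."""
    if len(hits) == 0 or (not taxonomy.blacklist and not taxonomy.masks):
        return hits
    keep = ~hits["sseqid"].isin(taxonomy.blacklist)
    if taxonomy.masks and {"sstart", "send"} <= set(hits.columns):
        for i in hits.index[keep]:
            acc = hits.at[i, "sseqid"]
            for m_start, m_end in taxonomy.masks.get(acc, ()):
                if _intervals_overlap(hits.at[i, "sstart"], hits.at[i, "send"],
                                      m_start, m_end):
                    keep.at[i] = False
                    break
    return hits[keep]


def lca_assign(retained: pd.DataFrame, taxonomy: Taxonomy,
               on_missing: str = "fail") -> ReadAssignment:
    """Assign one read to the lowest common ancestor of its retained hits.

    The assignment is the longest rank-prefix shared by every retained
    subject's lineage; disjoint lineages (e.g. one bacterial, one
    eukaryotic hit) give an empty prefix and the read is reported as
    unclassified at the root.  The percent identity of the top-scoring
    retained hit is carried along.

    ``on_missing`` controls subjects absent from the taxonomy:
    ``"fail"`` raises, ``"skip"`` ignores those hits.
    """
    if len(retained) == 0:
        raise ValueError("no retained hits to assign")
    read_id = retained["qseqid"].iloc[0]
    lineages = []
    known = []
    for _, row in retained.iterrows():
        acc = row["sseqid"]
        if acc not in taxonomy.lineages:
            if on_missing == "skip":
                continue
            raise KeyError(f"subject {acc!r} missing from taxonomy")
        lineages.append(taxonomy.lineages[acc])
        known.append(row)
    if not lineages:
        return ReadAssignment(read_id, (), "root", float("nan"))
    depth = min(len(lin) for lin in lineages)
    common = []
    for level in range(depth):
        taxa = {lin[level] for lin in lineages}
        if len(taxa) > 1:
            break
        common.append(lineages[0][level])
    top = max(known, key=lambda r: r["bitscore"])
    rank = RANKS[len(common) - 1] if common else "root"
    return ReadAssignment(read_id, tuple(common), rank, float(top["pident"]))


def assign_reads(hits: pd.DataFrame, taxonomy: Taxonomy, sample: str | None = None,
                 min_len: int = 100, min_bit: float = 50.0, window: float = 0.01,
                 on_missing: str = "fail") -> pd.DataFrame:
    """Run screening, retention and LCA for every read in a hit table.

    Returns one row per read: read_id, sample, lineage (semicolon
    joined), rank_achieved, top_pident.  Reads whose hits are all
    screened out are reported with an empty lineage at rank "root".
    If the hit table has a ``sample`` column it overrides the ``sample``
    argument per read.
    """
    screened = blacklist_filter(hits, taxonomy)
    rows = []
    sample_of = {}
    if "sample" in hits.columns:
        sample_of = hits.groupby("qseqid")["sample"].first().to_dict()
    all_reads = hits["qseqid"].unique()
    grouped = dict(iter(screened.groupby("qseqid"))) if len(screened) else {}
    for read_id in all_reads:
        sub = grouped.get(read_id)
        retained = retain_hits(sub, min_len, min_bit, window) if sub is not None else None
        if retained is None or len(retained) == 0:
            assignment = ReadAssignment(read_id, (), "root", float("nan"))
        else:
            assignment = lca_assign(retained, taxonomy, on_missing=on_missing)
        rows.append(
            {
                "read_id": read_id,
                "sample": sample_of.get(read_id, sample),
                "lineage": ";".join(assignment.lineage),
                "rank_achieved": assignment.rank_achieved,
                "top_pident": assignment.top_pident,
            }
        )
    return pd.DataFrame(rows)


class LCATaxonomyClassifier(BaseEstimator):
    """Estimator interface over the retained-hit LCA assignment rule.

    ``fit`` binds the reference :class:`Taxonomy`; ``predict`` maps a hit
    table to per-read assignments.  Useful for composing the profiling
    step in pipelines and for grid-searching retention thresholds.
    """

    def __init__(self, min_len: int = 100, min_bit: float = 50.0,
                 window: float = 0.01, on_missing: str = "fail"):
        self.min_len = min_len
        self.min_bit = min_bit
        self.window = window
        self.on_missing = on_missing

    def fit(self, taxonomy: Taxonomy, y=None):
        if not isinstance(taxonomy, Taxonomy):
            raise TypeError("fit expects a Taxonomy")
        self.taxonomy_ = taxonomy
        return self

    def predict(self, hits: pd.DataFrame, sample: str | None = None) -> pd.DataFrame:
        if not hasattr(self, "taxonomy_"):
            raise ValueError("classifier is not fitted; call fit(taxonomy) first")
        return assign_reads(hits, self.taxonomy_, sample=sample,
                            min_len=self.min_len, min_bit=self.min_bit,
                            window=self.window, on_missing=self.on_missing)


def _rank_index(rank: str) -> int:
    try:
        return RANKS.index(rank)
    except ValueError:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}") from None


def clade_table(assignments: pd.DataFrame, rank: str = "family",
                denominator_mode: str = "rank_assigned",
                domain: str | None = None) -> AbundanceTable:
    """Tabulate read assignments into a clade × sample count table.

    Reads assigned shallower than ``rank`` are excluded from the counts.
    ``domain`` optionally restricts the table (and the rank-assigned /
    domain denominators) to reads whose lineage starts with that domain.

    Denominator modes:

    * ``"rank_assigned"`` — reads assigned at ``rank`` (within ``domain``
      if given); proportions sum to 1 before rounding.
    * ``"domain"`` — all reads assigned at least a domain (restricted to
      ``domain`` if given).
    * ``"total"`` — every read in the sample, unassignable ones included.
    """
    idx = _rank_index(rank)
    df = assignments.copy()
    df["depth"] = df["lineage"].str.count(";").where(df["lineage"] != "", -1) + 1
    parts = df["lineage"].str.split(";")
    in_domain = pd.Series(True, index=df.index)
    if domain is not None:
        in_domain = (df["depth"] >= 1) & (parts.str[0] == domain)

    at_rank = (df["depth"] >= idx + 1) & in_domain
    sub = df[at_rank].copy()
    sub["clade"] = parts[at_rank].str[idx]
    counts = (
        sub.groupby(["clade", "sample"]).size().unstack(fill_value=0).sort_index()
    )
    all_samples = sorted(df["sample"].dropna().unique())
    counts = counts.reindex(columns=all_samples, fill_value=0)

    if denominator_mode == "rank_assigned":
        denom = counts.sum(axis=0)
    elif denominator_mode == "domain":
        denom = df[(df["depth"] >= 1) & in_domain].groupby("sample").size()
        denom = denom.reindex(all_samples, fill_value=0).astype(float)
    elif denominator_mode == "total":
        denom = df.groupby("sample").size().reindex(all_samples, fill_value=0).astype(float)
    else:
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    denom = denom.astype(float)
    return AbundanceTable(counts=counts, denominators=denom, rank=rank,
                          denominator_mode=denominator_mode)


def round_half_away(x, decimals: int):
    """Round half away from zero (numpy's default rounds half to even)."""
    factor = 10.0**decimals
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor


def round_normalize(table: AbundanceTable, decimals: int) -> AbundanceTable:
    """Round proportions to a fixed decimal resolution.

    Rounding to ``decimals`` places equalizes the effective resolution
    across libraries of different depth — comparable to rarefying each
    library to ~10^decimals reads, but deterministic.  Values below half
    the resolution become exactly 0.
    """
    if decimals < 1:
        raise ValueError("decimals must be >= 1")
    props = table.proportions
    table.normalized = pd.DataFrame(
        round_half_away(props.to_numpy(), decimals),
        index=props.index, columns=props.columns,
    )
    table.decimals = decimals
    return table


def sqrt_bray_nmds(table, dims: int = 2, seed: int = 0, n_init: int = 8):
    """Square-root transform, Bray-Curtis dissimilarity, non-metric MDS.

    ``table`` may be an :class:`AbundanceTable` (its rounded proportions,
    or plain proportions if not rounded, are used) or a sample × clade
    DataFrame.  Returns ``(coords, stress)`` where coords is a sample ×
    dimension DataFrame; the embedding seed and Kruskal stress (stress-1,
    normalized) are reported so ordinations are reproducible.
    """
    if isinstance(table, AbundanceTable):
        mat = table.values_for_tests().T  # samples x clades
    else:
        mat = pd.DataFrame(table)
    if mat.shape[0] < 3:
        raise ValueError("NMDS needs at least 3 samples")
    x = np.sqrt(mat.to_numpy(dtype=float))
    dist = pdist(x, metric="braycurtis")
    dist = np.nan_to_num(dist, nan=0.0)  # two all-zero samples are identical
    try:
        mds = MDS(
            n_components=dims, metric_mds=False, metric="precomputed",
            random_state=seed, n_init=n_init, normalized_stress=True,
            init="random",
        )
        coords = mds.fit_transform(squareform(dist))
    except TypeError:  # older sklearn parameter names
        mds = MDS(
            n_components=dims, metric=False, dissimilarity="precomputed",
            random_state=seed, n_init=n_init, normalized_stress=True,
        )
        coords = mds.fit_transform(squareform(dist))
    out = pd.DataFrame(coords, index=mat.index,
                       columns=[f"NMDS{i + 1}" for i in range(dims)])
    return out, float(mds.stress_)


def family_richness(table: AbundanceTable, threshold: float = 0.01,
                    groups: dict | None = None):
    """Per-sample count of clades above an abundance threshold.

    A clade is "present" when its (rounded) proportion exceeds
    ``threshold``.  With ``groups`` mapping sample → group label for two
    groups, also runs Welch's two-sample t-test on the richness values
    and returns ``(richness, result)`` where result has the t statistic,
    p-value and 95% CI of the mean difference; otherwise returns the
    richness Series alone.
    """
    vals = table.values_for_tests()
    richness = (vals > threshold).sum(axis=0)
    richness.name = "richness"
    if groups is None:
        return richness
    labels = pd.Series(groups)
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError("Welch comparison needs exactly two groups")
    a = richness[labels[labels == levels[0]].index].to_numpy(dtype=float)
    b = richness[labels[labels == levels[1]].index].to_numpy(dtype=float)
    res = stats.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval(0.95)
    result = {
        "group_a": levels[0], "group_b": levels[1],
        "mean_a": a.mean(), "mean_b": b.mean(),
        "t": float(res.statistic), "p": float(res.pvalue),
        "ci_low": float(ci.low), "ci_high": float(ci.high),
    }
    return richness, result


def clade_group_test(table: AbundanceTable, groups: dict,
                     fdr: float = 0.005) -> pd.DataFrame:
    """Per-clade two-group Mann-Whitney tests with BH FDR control.

    Tests each clade's rounded proportions between the two sample groups
    and flags clades with BH-adjusted p below ``fdr``.  Clades constant
    across all samples get p = 1 and are never flagged.
    """
    vals = table.values_for_tests()
    labels = pd.Series(groups).reindex(vals.columns)
    if labels.isna().any():
        raise ValueError("every sample needs a group label")
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError("need exactly two groups")
    a_cols = np.where(labels.to_numpy() == levels[0])[0]
    b_cols = np.where(labels.to_numpy() == levels[1])[0]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("need at least two samples per group")
    p = mannwhitney_table(vals.to_numpy(dtype=float), a_cols, b_cols)
    adj = bh_adjust(p)
    x = vals.to_numpy(dtype=float)
    out = pd.DataFrame(
        {
            "clade": vals.index,
            f"mean_{levels[0]}": x[:, a_cols].mean(axis=1),
            f"mean_{levels[1]}": x[:, b_cols].mean(axis=1),
            "p": p,
            "p_adjusted": adj,
        }
    ).set_index("clade")
    out["significant"] = out["p_adjusted"] < fdr
    return out


def mean_top_identity(assignments: pd.DataFrame, clade: str,
                      sample: str | None = None) -> float:
    """Mean top-hit percent identity of reads assigned within a clade.

    ``clade`` matches any rank of the assigned lineage.  Returns NaN when
    no read in the (optional) sample is assigned within the clade.
    """
    df = assignments
    if sample is not None:
        df = df[df["sample"] == sample]
    in_clade = df["lineage"].str.split(";").apply(lambda lin: clade in lin)
    vals = df.loc[in_clade, "top_pident"].dropna()
    if len(vals) == 0:
        warnings.warn(f"no reads assigned within {clade!r}", stacklevel=2)
        return float("nan")
    return float(vals.mean())
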
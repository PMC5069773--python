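"""KEGG-ortholog differential abundance between metagenome groups.

Protein-level alignment hits are first screened to reads of confidently
bacterial origin: a read passes only if *all* of its best-scoring hits
with alignment length >= 50 amino acids are to bacterial subjects.
Passing reads take the KO annotation of their single top-scoring hit.
KO counts per sample are converted to proportions of KO-assigned reads,
rounded to a fixed decimal place (equalizing depth like rarefaction,
deterministically), and compared between the two groups with per-KO
two-sided Mann-Whitney tests under Benjamini-Hochberg FDR control.
A KO is called enriched when its BH-adjusted p-value is below the FDR
threshold *and* the magnitude of its log2 fold change exceeds the
fold-change threshold.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .stats import bh_adjust, mannwhitney_table
from .taxonomy import round_half_away

__all__ = [
    "MannWhitneyDifferentialAbundance",
    "bacterial_read_filter",
    "ko_assign",
    "assign_kos",
    "ko_proportions",
    "ko_diff_test",
    "enrichment_summary",
    "read_ko_table",
    "read_group_map",
]


def bacterial_read_filter(hits: pd.DataFrame, min_len_aa: int = 50) -> set:
    """Reads whose best-scoring qualifying hits are all bacterial.

    ``hits`` needs columns qseqid, sseqid, length (amino acids),
    bitscore and domain (subject domain label).  A read with no
    qualifying hit, or with any non-bacterial subject tied at the best
    score, is excluded.
    """
    required = {"qseqid", "bitscore", "length", "domain"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    qual = hits[hits["length"] >= min_len_aa]
    if len(qual) == 0:
        return set()
    best = qual.groupby("qseqid")["bitscore"].transform("max")
    top = qual[qual["bitscore"] == best]
    all_bacterial = top.groupby("qseqid")["domain"].agg(lambda d: (d == "Bacteria").all())
    return set(all_bacterial.index[all_bacterial])


def ko_assign(read_hits: pd.DataFrame, ko_map: dict) -> str | None:
    """KO of the single top-scoring hit for one read.

    Returns ``None`` when the top hit has no KO annotation (lower hits
    are never consulted).  A score tie between subjects with conflicting
    KOs is broken deterministically toward the lowest KO id, with a
    warning; ties agreeing on the KO are silent.
    """
    if len(read_hits) == 0:
        return None
    best = read_hits["bitscore"].max()
    top = read_hits[read_hits["bitscore"] == best]
    annotations = [ko_map.get(s) for s in top["sseqid"]]
    if any(a is None for a in annotations):
        return None  # an unannotated subject is (part of) the top hit
    kos = sorted(set(annotations))
    if len(kos) > 1:
        warnings.warn(
            f"top-score tie with conflicting KOs {kos}; taking {kos[0]}", stacklevel=2
        )
    return kos[0]


def assign_kos(hits: pd.DataFrame, ko_map: dict, domain_map: dict | None = None,
               min_len_aa: int = 50) -> pd.DataFrame:
    """Bacterial-filter a protein hit table and tabulate KO counts per sample.

    ``hits`` follows the tabular aligner format with a ``sample`` column;
    the subject domain comes from a ``domain`` column or ``domain_map``.
    Returns a KO × sample count DataFrame.
    """
    hits = hits.copy()
    if "domain" not in hits.columns:
        if domain_map is None:
            raise ValueError("need a domain column or domain_map")
        hits["domain"] = hits["sseqid"].map(domain_map)
    bacterial = bacterial_read_filter(hits, min_len_aa=min_len_aa)
    rows = []
    for (read_id, sample), sub in hits.groupby(["qseqid", "sample"]):
        if read_id not in bacterial:
            continue
        ko = ko_assign(sub, ko_map)
        if ko is not None:
            rows.append((ko, sample))
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows, columns=["ko", "sample"])
    return df.groupby(["ko", "sample"]).size().unstack(fill_value=0).sort_index()


def ko_proportions(counts: pd.DataFrame, decimals: int = 5) -> pd.DataFrame:
    """Per-sample proportions of KO-assigned reads, rounded.

    Rounding to 5 decimals approximates rarefying every library to
    ~100,000-scale read depth without resampling noise.
    """
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero-total samples: {bad}")
    props = counts.div(totals, axis=1)
    return pd.DataFrame(
        round_half_away(props.to_numpy(), decimals),
        index=props.index, columns=props.columns,
    )


def ko_diff_test(normalized: pd.DataFrame, groups: dict, fdr: float = 0.005,
                 lfc_threshold: float = 2.0, group_order: tuple | None = None,
                 test=None) -> pd.DataFrame:
    """Per-KO two-group comparison on rounded proportions.

    For each KO present in at least one sample: a two-sided Mann-Whitney
    test between the groups, BH adjustment across all tested KOs, and a
    log2 fold change of group means with a symmetric pseudocount (half
    the smallest nonzero proportion in the table).  Flags:

    * ``enriched_up`` — adjusted p < ``fdr`` and log2FC > ``lfc_threshold``
      (more abundant in the first group),
    * ``enriched_down`` — adjusted p < ``fdr`` and log2FC < -``lfc_threshold``.

    ``group_order`` fixes which group is the fold-change numerator
    (default: sorted label order).  ``test`` optionally replaces the
    Mann-Whitney p-value computation with an external per-feature test
    ``test(matrix, a_cols, b_cols) -> p-values`` (e.g. a negative-
    binomial model adapter); the BH/flagging path is unchanged.
    """
    labels = pd.Series(groups).reindex(normalized.columns)
    if labels.isna().any():
        raise ValueError("every sample needs a group label")
    levels = list(group_order) if group_order is not None else sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError("need exactly two groups")
    a_cols = np.where(labels.to_numpy() == levels[0])[0]
    b_cols = np.where(labels.to_numpy() == levels[1])[0]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("need at least two samples per group")

    present = normalized.sum(axis=1) > 0
    tested = normalized[present]
    x = tested.to_numpy(dtype=float)
    pfun = test if test is not None else mannwhitney_table
    p = pfun(x, a_cols, b_cols)
    adj = bh_adjust(p)

    nonzero = x[x > 0]
    pseudo = 0.5 * nonzero.min() if nonzero.size else 0.5
    mean_a = x[:, a_cols].mean(axis=1)
    mean_b = x[:, b_cols].mean(axis=1)
    lfc = np.log2((mean_a + pseudo) / (mean_b + pseudo))

    out = pd.DataFrame(
        {
            f"mean_{levels[0]}": mean_a,
            f"mean_{levels[1]}": mean_b,
            "log2fc": lfc,
            "p": p,
            "p_adjusted": adj,
        },
        index=tested.index,
    )
    sig = out["p_adjusted"] < fdr
    out["enriched_up"] = sig & (out["log2fc"] > lfc_threshold)
    out["enriched_down"] = sig & (out["log2fc"] < -lfc_threshold)
    out.attrs["groups"] = levels
    return out


def enrichment_summary(result: pd.DataFrame) -> dict:
    """Counts and display percentages of enriched KOs per direction.

    Percentages are 100 x n / n_tested, rounded to the nearest integer
    for display (e.g. 1,064 of 5,912 KOs → 18%).
    """
    n_tested = len(result)
    n_up = int(result["enriched_up"].sum())
    n_down = int(result["enriched_down"].sum())
    pct = lambda n: int(round(100.0 * n / n_tested)) if n_tested else 0  # noqa: E731
    return {
        "n_tested": n_tested,
        "n_up": n_up,
        "n_down": n_down,
        "pct_up": pct(n_up),
        "pct_down": pct(n_down),
    }


class MannWhitneyDifferentialAbundance(BaseEstimator):
    """Rank-based differential abundance on rounded count proportions.

    The estimator normalizes a feature × sample count table to per-sample
    proportions rounded at ``decimals`` places, runs per-feature
    Mann-Whitney tests with BH FDR control, and flags features passing
    both the FDR and |log2FC| thresholds.  Fitted attributes:
    ``normalized_``, ``results_``, ``summary_``.
    """

    def __init__(self, fdr: float = 0.005, lfc_threshold: float = 2.0,
                 decimals: int = 5, group_order: tuple | None = None, test=None):
        self.fdr = fdr
        self.lfc_threshold = lfc_threshold
        self.decimals = decimals
        self.group_order = group_order
        self.test = test

    def fit(self, X: pd.DataFrame, y):
        """``X``: feature × sample counts; ``y``: sample → group mapping."""
        groups = dict(y) if not isinstance(y, dict) else y
        self.normalized_ = ko_proportions(X, decimals=self.decimals)
        self.results_ = ko_diff_test(
            self.normalized_, groups, fdr=self.fdr,
            lfc_threshold=self.lfc_threshold, group_order=self.group_order,
            test=self.test,
        )
        self.summary_ = enrichment_summary(self.results_)
        return self


def read_ko_table(path) -> pd.DataFrame:
    """Read a KO × sample count TSV (KO ids in the first column)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_group_map(path) -> dict:
    """Read a sample → group TSV (two columns, no header required)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.iloc[0, 0] == "sample":
        df = df.iloc[1:]
    return dict(zip(df[0], df[1]))
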
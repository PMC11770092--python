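"""Missing-value-aware presence and differential screening of proteomes.

Processed tumor proteomes (CPTAC-style) arrive as protein x sample
intensity matrices in which a missing cell means the protein was not
quantified in that run. Two screens operate on such matrices:

* the presence rule — a protein counts as identified in a cohort when it
  is quantified in strictly more than ``presence_frac`` (default 30%) of
  that cohort's tumor samples OR of its non-tumor samples;
* the differential screen — proteins quantified in strictly more than
  ``de_presence_frac`` (default 50%) of BOTH groups are tested for a
  tumor/non-tumor difference. The fold change is the ratio of linear-scale
  group means over observed values (no imputation); the test runs on log2
  intensities, choosing an unpaired pooled-variance Student's t when both
  groups pass a Shapiro-Wilk normality pre-test and a two-sided
  Mann-Whitney U otherwise. A protein is significant at p < ``alpha`` and
  |fold change| >= ``fc_cut`` (default 1.5), on raw p by default with
  optional Benjamini-Hochberg correction.

Pan-cancer set analysis (core proteins identified in every cohort vs
proteins unique to one cohort) reproduces the flower-plot logic used for
catalogues of lncRNA-encoded proteins.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AbundanceMatrix",
    "ScreenConfig",
    "PresenceCall",
    "DEResult",
    "call_presence",
    "identified_sets",
    "pan_cancer_sets",
    "differential_expression",
    "length_histogram",
    "read_abundance",
    "write_presence_table",
    "write_de_table",
    "write_set_summary",
]

GROUPS = ("tumor", "nontumor")


@dataclass
class AbundanceMatrix:
    """Protein x sample intensities (NaN = missing) plus sample metadata.

    ``values``: DataFrame indexed by protein accession, columns = sample ids.
    ``sample_meta``: DataFrame indexed by sample id with columns
    ``cohort``, ``group`` (tumor | nontumor) and optional ``pair_id``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        v, m = self.values, self.sample_meta
        if v.index.has_duplicates:
            raise ValueError("duplicate protein accessions")
        if v.columns.has_duplicates or m.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if set(v.columns) != set(m.index):
            raise ValueError("sample ids in matrix and metadata differ")
        if not set(m["group"]).issubset(GROUPS):
            bad = sorted(set(m["group"]) - set(GROUPS))
            raise ValueError(f"unknown group labels: {bad}")
        if m["cohort"].isna().any():
            raise ValueError("every sample needs a cohort label")
        vals = v.to_numpy(dtype=float)
        if (vals <= 0).any():  # NaN compares False: missing cells pass
            raise ValueError("present intensities must be positive")
        self.sample_meta = m.loc[v.columns]

    @property
    def cohorts(self) -> list[str]:
        return sorted(self.sample_meta["cohort"].unique())

    def samples_of(self, cohort: str, group: str) -> list[str]:
        m = self.sample_meta
        return list(m.index[(m["cohort"] == cohort) & (m["group"] == group)])


@dataclass(frozen=True)
class ScreenConfig:
    presence_frac: float = 0.30
    de_presence_frac: float = 0.50
    fc_cut: float = 1.5
    alpha: float = 0.05
    normality_alpha: float = 0.05
    paired: bool = False
    welch: bool = False
    bh_correct: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.presence_frac < 1 or not 0 < self.de_presence_frac < 1:
            raise ValueError("presence fractions must lie in (0, 1)")
        if self.fc_cut <= 1:
            raise ValueError("fc_cut must exceed 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class PresenceCall:
    protein: str
    cohort: str
    frac_tumor: float
    frac_nontumor: float
    identified: bool


@dataclass(frozen=True)
class DEResult:
    protein: str
    log2fc: float
    p_value: float
    test_used: str  # student_t | mann_whitney | (skipped)
    significant: bool
    skip_reason: str = ""
    n_tumor: int = 0
    n_nontumor: int = 0


def call_presence(
    matrix: AbundanceMatrix,
    config: ScreenConfig = ScreenConfig(),
    cohorts: Sequence[str] | None = None,
) -> list[PresenceCall]:
    """One presence call per protein per cohort (strict > rule).

    ``cohorts`` restricts (or extends) which cohorts are evaluated;
    requesting a cohort with no samples in either group is an error.
    """
    calls: list[PresenceCall] = []
    for cohort in (matrix.cohorts if cohorts is None else cohorts):
        tum = matrix.samples_of(cohort, "tumor")
        non = matrix.samples_of(cohort, "nontumor")
        if not tum and not non:
            raise ValueError(f"cohort {cohort!r} has no samples in either group")
        ft = matrix.values[tum].notna().mean(axis=1) if tum else pd.Series(0.0, index=matrix.values.index)
        fn = matrix.values[non].notna().mean(axis=1) if non else pd.Series(0.0, index=matrix.values.index)
        for prot in matrix.values.index:
            t, n = float(ft[prot]), float(fn[prot])
            calls.append(
                PresenceCall(
                    protein=prot,
                    cohort=cohort,
                    frac_tumor=t,
                    frac_nontumor=n,
                    identified=(t > config.presence_frac) or (n > config.presence_frac),
                )
            )
    return calls


def identified_sets(calls: Iterable[PresenceCall]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for c in calls:
        out.setdefault(c.cohort, set())
        if c.identified:
            out[c.cohort].add(c.protein)
    return out


def pan_cancer_sets(
    identified: Mapping[str, set[str]],
) -> tuple[set[str], dict[str, set[str]], dict[str, int]]:
    """Flower-plot decomposition of per-cohort identification sets.

    Returns (core, unique, per_cohort_counts): core = proteins identified
    in all cohorts; unique[c] = proteins identified in cohort c only.
    """
    if not identified:
        raise ValueError("need at least one cohort")
    cohorts = sorted(identified)
    core = set.intersection(*(set(identified[c]) for c in cohorts))
    unique: dict[str, set[str]] = {}
    for c in cohorts:
        others = set().union(*(identified[o] for o in cohorts if o != c)) if len(cohorts) > 1 else set()
        unique[c] = set(identified[c]) - others
    counts = {c: len(identified[c]) for c in cohorts}
    return core, unique, counts


def _is_normal(log_vals: np.ndarray, alpha: float) -> bool:
    """Shapiro-Wilk pre-test; degenerate (constant or tiny) samples are
    treated as non-normal and routed to the rank test."""
    if len(log_vals) < 3 or np.ptp(log_vals) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return stats.shapiro(log_vals).pvalue > alpha


def differential_expression(
    matrix: AbundanceMatrix,
    config: ScreenConfig = ScreenConfig(),
    cohort: str | None = None,
) -> list[DEResult]:
    """Tumor vs non-tumor screen; ``cohort=None`` pools all samples."""
    meta = matrix.sample_meta
    mask = meta["cohort"] == cohort if cohort is not None else pd.Series(True, index=meta.index)
    tum = list(meta.index[mask & (meta["group"] == "tumor")])
    non = list(meta.index[mask & (meta["group"] == "nontumor")])
    results: list[DEResult] = []
    log2fc_cut = math.log2(config.fc_cut)
    for prot in matrix.values.index:
        xt = matrix.values.loc[prot, tum].dropna().to_numpy(dtype=float) if tum else np.array([])
        xn = matrix.values.loc[prot, non].dropna().to_numpy(dtype=float) if non else np.array([])
        ft = len(xt) / len(tum) if tum else 0.0
        fn = len(xn) / len(non) if non else 0.0
        if len(xt) == 0 and len(xn) == 0:
            results.append(DEResult(prot, float("nan"), float("nan"), "", False, "all_missing"))
            continue
        if ft <= config.de_presence_frac or fn <= config.de_presence_frac:
            results.append(
                DEResult(prot, float("nan"), float("nan"), "", False,
                         "below_de_presence_frac", len(xt), len(xn))
            )
            continue
        if len(xt) < 3 or len(xn) < 3:
            results.append(
                DEResult(prot, float("nan"), float("nan"), "", False,
                         "fewer_than_3_observed", len(xt), len(xn))
            )
            continue
        log2fc = float(np.log2(xt.mean() / xn.mean()))
        lt, ln = np.log2(xt), np.log2(xn)
        if config.paired:
            p, test = _paired_test(matrix, prot, meta, mask, config)
        elif _is_normal(lt, config.normality_alpha) and _is_normal(ln, config.normality_alpha):
            p = float(stats.ttest_ind(lt, ln, equal_var=not config.welch).pvalue)
            test = "student_t"
        else:
            p = float(stats.mannwhitneyu(lt, ln, alternative="two-sided").pvalue)
            test = "mann_whitney"
        results.append(DEResult(prot, log2fc, p, test, False, "", len(xt), len(xn)))
    tested = [r for r in results if not r.skip_reason]
    pvals = np.array([r.p_value for r in tested])
    if config.bh_correct and len(pvals):
        pvals = multipletests(pvals, method="fdr_bh")[1]
    out: list[DEResult] = [r for r in results if r.skip_reason]
    for r, p in zip(tested, pvals):
        sig = bool(p < config.alpha and abs(r.log2fc) >= log2fc_cut)
        out.append(DEResult(r.protein, r.log2fc, float(p), r.test_used, sig,
                            "", r.n_tumor, r.n_nontumor))
    order = {p: i for i, p in enumerate(matrix.values.index)}
    out.sort(key=lambda r: order[r.protein])
    return out


def _paired_test(matrix, prot, meta, mask, config) -> tuple[float, str]:
    sub = meta[mask].dropna(subset=["pair_id"])
    # Pair tumor/nontumor samples by pair_id; drop incomplete pairs.
    by_pair: dict[str, dict[str, float]] = {}
    for sid, row in sub.iterrows():
        val = matrix.values.at[prot, sid]
        if pd.notna(val):
            by_pair.setdefault(row["pair_id"], {})[row["group"]] = float(val)
    t, n = zip(*[
        (d["tumor"], d["nontumor"]) for d in by_pair.values() if len(d) == 2
    ]) if any(len(d) == 2 for d in by_pair.values()) else ((), ())
    lt, ln = np.log2(np.array(t)), np.log2(np.array(n))
    if len(lt) < 3:
        return float("nan"), "too_few_pairs"
    diff = lt - ln
    if _is_normal(diff, config.normality_alpha):
        return float(stats.ttest_rel(lt, ln).pvalue), "student_t"
    return float(stats.wilcoxon(lt, ln).pvalue), "mann_whitney"


def length_histogram(
    lengths_aa: Sequence[int], bin_edges: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Counts and fractions of product lengths per bin (edges half-open,
    last bin closed, as in numpy)."""
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    lengths = np.asarray(lengths_aa)
    if len(lengths) and lengths.min() <= 0:
        raise ValueError("lengths must be positive")
    counts, _ = np.histogram(lengths, bins=edges)
    total = counts.sum()
    fracs = counts / total if total else np.zeros_like(counts, dtype=float)
    return counts, fracs


# ---------------------------------------------------------------- file IO

def read_abundance(values_path: str | Path, meta_path: str | Path) -> AbundanceMatrix:
    """Abundance TSV (first column = accession; empty cell or NA = missing)
    plus sample-metadata TSV (sample_id, cohort, group[, pair_id])."""
    values = pd.read_csv(values_path, sep="\t", index_col=0, comment="#",
                         na_values=["NA", ""])
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, comment="#", dtype=str)
    return AbundanceMatrix(values, meta)


def write_presence_table(calls: Iterable[PresenceCall], out: str | Path) -> int:
    rows = [
        f"{c.protein}\t{c.cohort}\t{c.frac_tumor:.6g}\t{c.frac_nontumor:.6g}\t{str(c.identified).lower()}"
        for c in calls
    ]
    header = "protein\tcohort\tfrac_tumor\tfrac_nontumor\tidentified"
    Path(out).write_text("\n".join([header, *rows]) + "\n")
    return len(rows)


def write_de_table(results: Iterable[DEResult], out: str | Path) -> int:
    rows = [
        f"{r.protein}\t{r.log2fc:.6g}\t{r.p_value:.6g}\t{r.test_used}\t"
        f"{str(r.significant).lower()}\t{r.skip_reason}"
        for r in results
    ]
    header = "protein\tlog2fc\tp_value\ttest_used\tsignificant\tskip_reason"
    Path(out).write_text("\n".join([header, *rows]) + "\n")
    return len(rows)


def write_set_summary(
    core: set[str], unique: Mapping[str, set[str]], counts: Mapping[str, int], out: str | Path
) -> None:
    payload = {
        "core": sorted(core),
        "core_count": len(core),
        "unique": {c: sorted(s) for c, s in sorted(unique.items())},
        "unique_counts": {c: len(s) for c, s in sorted(unique.items())},
        "per_cohort_counts": dict(sorted(counts.items())),
    }
    Path(out).write_text(json.dumps(payload, indent=2) + "\n")
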
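"""Branch-rate tables and the statistical comparisons of the study design.

Absolute synonymous/nonsynonymous rates per branch (R_S = dS/dt, R_N =
dN/dt, substitutions/site/My) are compared between intron-containing
(type I) and intron-less (type II) lineages with Wilcoxon rank-sum tests,
as are per-branch transition/transversion counts (TI, TV).  Likelihood-ratio
tests compare one-parameter null models against models with a second
branch-class parameter (dN/dS under MG94xHKY85; kappa under HKY85), and the
exon-region analysis contrasts single-copy (SC) vs inverted-repeat (IR)
codons both by pairwise distances against outgroups and by one-rate vs
two-rate partitioned LRTs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .gene_model import CodonAlignment
from .likelihood import (
    FitResult,
    LRTResult,
    fit_hky,
    fit_mg94,
    lrt,
    pairwise_hky,
    pairwise_ml,
)
from .phylo import Node, Tree
from .subst_models import decompose_sn, decompose_titv, HKYParams

__all__ = [
    "TestReport",
    "DegenerateSampleError",
    "classify_branches",
    "absolute_rates",
    "wilcoxon_rank_sum",
    "compare_type_rates",
    "type_lrt",
    "region_pairwise",
    "region_tests",
]

EXACT_LIMIT = 16  # enumerate the null when n+m <= this and there are no ties
MIN_DT_MY = 0.1  # branches shorter than this (My) are flagged, not divided


class DegenerateSampleError(ValueError):
    pass


@dataclass
class TestReport:
    comparison: str
    statistic: float
    p_value: float
    n_x: int
    n_y: int
    method: str
    direction: Optional[str] = None  # sign of median(x) - median(y)


# --------------------------------------------------------------------------
# branch classification
# --------------------------------------------------------------------------


def classify_branches(tree: Tree, tip_type_map: Mapping[str, str]) -> Tree:
    """Label every branch typeI/typeII from tip gene types.

    A branch is typeII iff *all* its descendant tips carry type-II (intron-
    less) genes, so the stem branch of each type-II clade is included;
    everything else is typeI.  Returns a labeled copy.
    """
    missing = [t for t in tree.leaf_names() if t not in tip_type_map]
    if missing:
        raise ValueError(f"tips without a gene-type label: {missing}")
    work = tree.copy()
    all2: dict[int, bool] = {}
    for node in work.postorder():
        if node.is_leaf:
            all2[node.index] = tip_type_map[node.name] == "II"
        else:
            all2[node.index] = all(all2[c.index] for c in node.children)
        node.klass = "typeII" if all2[node.index] else "typeI"
    return work


# --------------------------------------------------------------------------
# absolute rates
# --------------------------------------------------------------------------


def absolute_rates(
    dS_tree: Tree,
    dN_tree: Tree,
    chronogram,
    titv_tree: Optional[Tree] = None,
    min_dt: float = MIN_DT_MY,
) -> pd.DataFrame:
    """Per-branch table of dt, dS, dN, R_S, R_N (and TI/TV when provided).

    The three (or four) trees must share one topology; branches are matched
    by their descendant tip sets.  Branches with dt below ``min_dt`` My are
    flagged and their rates set to NaN rather than divided.
    """
    chron_tree = chronogram.tree if hasattr(chronogram, "tree") else chronogram
    ds_map = _branch_map(dS_tree)
    dn_map = _branch_map(dN_tree)
    ti_map = _branch_map(titv_tree) if titv_tree is not None else None
    rows = []
    for node in chron_tree.branches():
        key = chron_tree.clade_key(node)
        if key not in ds_map or key not in dn_map:
            raise ValueError(
                f"topology mismatch: branch {sorted(key)} absent from rate trees"
            )
        dt = node.parent.age - node.age
        ds = ds_map[key].length
        dn = dn_map[key].length
        flagged = dt < min_dt
        row = dict(
            clade="|".join(sorted(key)),
            branch_class=node.klass or ds_map[key].klass or "all",
            dt_my=dt,
            dS=ds,
            dN=dn,
            R_S=np.nan if flagged else ds / dt,
            R_N=np.nan if flagged else dn / dt,
            flagged=flagged,
        )
        if ti_map is not None:
            tnode = ti_map[key]
            row["TI"] = getattr(tnode, "ti", np.nan)
            row["TV"] = getattr(tnode, "tv", np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def _branch_map(tree: Tree) -> dict[frozenset, Node]:
    return {k: n for k, n in tree.clade_map().items() if not n.is_root}


def attach_titv(tree: Tree, fit: FitResult) -> Tree:
    """Annotate a tree's branches with expected TI/TV per site from a local
    (per-branch kappa) HKY fit."""
    work = tree.copy()
    kap_map = fit.params.get("kappa_by_branch")
    base = HKYParams(kappa=2.0, pi=fit.params["pi"])
    fit_map = _branch_map(fit.tree)
    cm = work.clade_map()
    for key, node in cm.items():
        if node.is_root:
            continue
        t = fit_map[key].length
        kappa = kap_map[key] if kap_map else fit.params["kappa"]
        ti, tv = decompose_titv(base, t, kappa=kappa)
        node.ti, node.tv = ti, tv  # type: ignore[attr-defined]
    return work


# --------------------------------------------------------------------------
# Wilcoxon rank-sum
# --------------------------------------------------------------------------


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    comparison: str = "",
) -> TestReport:
    """Rank-sum test of two independent samples.

    The exact null distribution of the rank sum of ``x`` is enumerated when
    n+m <= 16 and there are no ties; otherwise the tie-corrected normal
    approximation with continuity correction is used.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    n, m = len(x), len(y)
    w_obs = _rank_sum_of_x(x, y)
    direction = _direction(x, y)
    if n + m <= EXACT_LIMIT and not has_ties:
        p = _exact_rank_sum_p(w_obs, n, m, alternative)
        return TestReport(comparison, w_obs, p, n, m, "wilcoxon_exact", direction)
    res = mannwhitneyu(
        x, y, alternative=alternative, method="asymptotic", use_continuity=True
    )
    return TestReport(
        comparison, w_obs, float(res.pvalue), n, m, "wilcoxon_normal", direction
    )


def _rank_sum_of_x(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    order = pooled.argsort(kind="mergesort")
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    # midranks for ties
    vals, inv, counts = np.unique(pooled, return_inverse=True, return_counts=True)
    cum = np.cumsum(counts)
    mid = cum - (counts - 1) / 2.0
    ranks = mid[inv]
    return float(ranks[: len(x)].sum())


def _exact_rank_sum_p(w_obs: float, n: int, m: int, alternative: str) -> float:
    total = n + m
    sums = [sum(c) for c in itertools.combinations(range(1, total + 1), n)]
    sums = np.asarray(sums, dtype=float)
    ncomb = len(sums)
    p_le = np.count_nonzero(sums <= w_obs + 1e-9) / ncomb
    p_ge = np.count_nonzero(sums >= w_obs - 1e-9) / ncomb
    if alternative == "less":
        return p_le
    if alternative == "greater":
        return p_ge
    if alternative == "two-sided":
        return min(1.0, 2.0 * min(p_le, p_ge))
    raise ValueError(f"unknown alternative {alternative!r}")


def _direction(x: np.ndarray, y: np.ndarray) -> str:
    d = np.median(x) - np.median(y)
    return "x>y" if d > 0 else ("x<y" if d < 0 else "x=y")


# --------------------------------------------------------------------------
# type-I vs type-II comparisons
# --------------------------------------------------------------------------


def holm_adjust(reports: Sequence[TestReport]) -> list[TestReport]:
    """Holm step-down adjustment of a family of test reports (off by
    default: raw p-values are reported unless explicitly requested)."""
    order = np.argsort([r.p_value for r in reports])
    m = len(reports)
    adjusted = [None] * m
    running = 0.0
    for rank, idx in enumerate(order):
        p = min(1.0, (m - rank) * reports[idx].p_value)
        running = max(running, p)
        r = reports[idx]
        adjusted[idx] = TestReport(
            r.comparison, r.statistic, running, r.n_x, r.n_y,
            r.method + "+holm", r.direction,
        )
    return adjusted


def compare_type_rates(
    rate_table: pd.DataFrame,
    quantities: Sequence[str] = ("R_S", "R_N", "TI", "TV"),
    adjust: str = "none",
) -> list[TestReport]:
    """Wilcoxon rank-sum of each rate quantity between typeII (x) and typeI
    (y) branches; flagged branches and NaNs are excluded.  ``adjust='holm'``
    applies a Holm correction across the family (raw p-values by default)."""
    reports = []
    if "flagged" in rate_table.columns:
        usable = rate_table[~rate_table["flagged"].astype(bool)]
    else:
        usable = rate_table
    for q in quantities:
        if q not in usable.columns:
            continue
        sub = usable.dropna(subset=[q])
        x = sub.loc[sub.branch_class == "typeII", q].to_numpy()
        y = sub.loc[sub.branch_class == "typeI", q].to_numpy()
        if len(x) < 2 or len(y) < 2:
            raise DegenerateSampleError(
                f"{q}: need >= 2 branches per class (got {len(x)} typeII, "
                f"{len(y)} typeI)"
            )
        reports.append(
            wilcoxon_rank_sum(x, y, comparison=f"{q}: typeII vs typeI")
        )
    if adjust == "holm":
        reports = holm_adjust(reports)
    elif adjust != "none":
        raise ValueError(f"unknown adjustment {adjust!r}")
    return reports


def type_lrt(
    alignment,
    tree: Tree,
    tip_type_map: Mapping[str, str],
    quantity: str = "omega",
) -> tuple[LRTResult, FitResult, FitResult]:
    """df=1 LRT for a branch-class effect.

    quantity='omega': MG94xHKY85, one shared dN/dS (null) vs separate type-I
    and type-II dN/dS (alternative).  quantity='titv': HKY85, shared kappa vs
    class-specific kappa.  Returns (LRT, null fit, alternative fit).
    """
    labeled = classify_branches(tree, tip_type_map)
    if quantity == "omega":
        fit0 = fit_mg94(labeled, alignment, omega_mode="global")
        fit1 = fit_mg94(labeled, alignment, omega_mode="by_class")
    elif quantity == "titv":
        rows = _nt_rows(alignment)
        fit0 = fit_hky(labeled, rows, kappa_mode="global")
        fit1 = fit_hky(labeled, rows, kappa_mode="by_class")
    else:
        raise ValueError(f"unknown quantity {quantity!r}")
    return lrt(fit0, fit1, df=1), fit0, fit1


def _nt_rows(alignment) -> dict[str, str]:
    if isinstance(alignment, CodonAlignment):
        return dict(zip(alignment.taxa, alignment.to_nucleotides()))
    return dict(alignment)


# --------------------------------------------------------------------------
# SC vs IR region analysis
# --------------------------------------------------------------------------


def region_pairwise(
    fern_cds: Mapping[str, Sequence[str]],
    outgroup_cds: Mapping[str, Sequence[str]],
    partition: Sequence[str],
    min_codons: int = 10,
) -> pd.DataFrame:
    """Pairwise ML distances per (fern, outgroup, region).

    Inputs are codon rows (aligned, gap-free) and a per-codon SC/IR label
    vector.  For each region the codon columns are concatenated and a
    two-sequence MG94 fit yields dS (and dN); a two-sequence HKY fit on the
    same nucleotides yields expected TI and TV per site.
    """
    if not outgroup_cds:
        raise ValueError("at least one outgroup is required")
    regions = sorted(set(partition))
    idx_by_region = {
        r: [i for i, p in enumerate(partition) if p == r] for r in regions
    }
    import warnings

    for r, idx in idx_by_region.items():
        if len(idx) < min_codons:
            warnings.warn(
                f"region {r} has only {len(idx)} codons; pairwise estimates "
                f"will be noisy"
            )
    rows = []
    for fern, frow in fern_cds.items():
        for og, orow in outgroup_cds.items():
            for region in regions:
                idx = idx_by_region[region]
                a = "".join(frow[i] for i in idx)
                b = "".join(orow[i] for i in idx)
                codon_res = pairwise_ml(a, b)
                nt_res = pairwise_hky(a, b)
                rows.append(
                    dict(
                        taxon=fern,
                        outgroup=og,
                        region=region,
                        n_codons=len(idx),
                        t=codon_res.t,
                        dS=codon_res.dS,
                        dN=codon_res.dN,
                        omega=codon_res.omega,
                        TI=nt_res.TI,
                        TV=nt_res.TV,
                        saturated=codon_res.saturated,
                    )
                )
    return pd.DataFrame(rows)


def region_tests(
    region_table: pd.DataFrame,
    alignment: Optional[CodonAlignment] = None,
    tree: Optional[Tree] = None,
    paired: bool = False,
) -> dict:
    """SC-vs-IR comparisons: Wilcoxon rank-sum of pairwise dS, TI and TV
    between regions, plus (when alignment+tree are given) the one-rate vs
    two-rate partitioned LRTs (MG94 omega; HKY kappa), each df=1.

    The rank-sum test is run unpaired by default, matching the named test of
    the comparative design even though the rows pair per (taxon, outgroup);
    ``paired=True`` switches to the signed-rank test on per-pair IR-SC
    differences.
    """
    if region_table.empty:
        raise ValueError("region table is empty")
    out: dict = {"wilcoxon": [], "lrt": {}}
    if paired:
        import logging

        logging.getLogger(__name__).info(
            "using paired signed-rank test on per-(taxon,outgroup) IR-SC "
            "differences instead of the unpaired rank-sum test"
        )
    for q in ("dS", "TI", "TV"):
        sub = region_table.dropna(subset=[q])
        if paired:
            wide = sub.pivot_table(
                index=["taxon", "outgroup"], columns="region", values=q
            )
            diffs = (wide["IR"] - wide["SC"]).to_numpy()
            from scipy.stats import wilcoxon as signed_rank

            if np.allclose(diffs, 0.0):
                stat, p = 0.0, 1.0
            else:
                stat, p = signed_rank(diffs)
            med = float(np.median(diffs))
            out["wilcoxon"].append(
                TestReport(
                    f"{q}: IR vs SC", float(stat), float(p),
                    len(diffs), len(diffs), "wilcoxon_signed_rank",
                    "x>y" if med > 0 else ("x<y" if med < 0 else "x=y"),
                )
            )
            continue
        x = sub.loc[sub.region == "IR", q].to_numpy()
        y = sub.loc[sub.region == "SC", q].to_numpy()
        out["wilcoxon"].append(
            wilcoxon_rank_sum(x, y, comparison=f"{q}: IR vs SC")
        )
    if alignment is not None and tree is not None:
        if alignment.partition is None:
            raise ValueError("partitioned LRTs need a partitioned alignment")
        fit0 = fit_mg94(tree, alignment, omega_mode="global")
        fit1 = fit_mg94(tree, alignment, omega_mode="by_region")
        # the two-rate fit frees one extra omega and one region rate
        # multiplier; the omega contrast is the df=1 comparison of interest,
        # so the null is refit with the multiplier free as well
        fit0b = _fit_mg94_shared_omega_region(tree, alignment)
        out["lrt"]["omega_region"] = lrt(fit0b, fit1, df=1)
        rows = _nt_rows(alignment)
        region_rows = [
            dict(
                zip(
                    alignment.taxa,
                    alignment.subset_partition(lab).to_nucleotides(),
                )
            )
            for lab in sorted(set(alignment.partition))
        ]
        h0 = fit_hky(tree, rows, kappa_mode="global", partition_rows=region_rows)
        h1 = fit_hky(tree, rows, kappa_mode="by_region", partition_rows=region_rows)
        out["lrt"]["titv_region"] = lrt(h0, h1, df=1)
    return out


def _fit_mg94_shared_omega_region(tree: Tree, aln: CodonAlignment) -> FitResult:
    """Null for the region LRT: shared omega across regions but a free
    region rate multiplier (so the alternative adds exactly one parameter)."""
    import numpy as np

    from .likelihood import (
        DEFAULT_CLASS,
        LOG_PARAM_BOUNDS,
        _BranchModel,
        _FitProblem,
        _sanitize_lengths,
        _scaled_matrix,
        encode_codons,
    )
    from .subst_models import MG94Params, mg94_matrix, position_frequencies

    labels = sorted(set(aln.partition))
    sub = [aln.subset_partition(lab) for lab in labels]
    parts = [encode_codons(s) for s in sub]
    pos_freqs = position_frequencies(aln.rows)
    classes = sorted({(n.klass or DEFAULT_CLASS) for n in tree.branches()})
    names = ["kappa", "omega"] + [f"rate:{lab}" for lab in labels[1:]]

    def builder(theta):
        vals = dict(zip(names, np.exp(theta)))
        models = []
        for lab in labels:
            mp = MG94Params(
                kappa=vals["kappa"],
                omega_by_class={c: vals["omega"] for c in classes},
                pos_freqs=pos_freqs,
            )
            mult = vals.get(f"rate:{lab}", 1.0)
            models.append(
                _BranchModel(
                    {c: _scaled_matrix(mg94_matrix(mp, c), mult) for c in classes}
                )
            )
        return models

    work = tree.copy()
    _sanitize_lengths(work)
    theta0 = np.concatenate([[np.log(2.0), np.log(0.2)], np.zeros(len(labels) - 1)])
    problem = _FitProblem(
        work, parts, builder, theta0, [LOG_PARAM_BOUNDS] * len(names), names
    )
    lnL, converged = problem.run()
    vals = dict(zip(names, np.exp(problem.theta)))
    params = {"kappa": vals["kappa"], "omega": vals["omega"]}
    model = MG94Params(
        kappa=vals["kappa"],
        omega_by_class={c: vals["omega"] for c in classes},
        pos_freqs=pos_freqs,
    )
    return FitResult(
        work, params, lnL, len(names) + len(work.branches()), converged, model
    )
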
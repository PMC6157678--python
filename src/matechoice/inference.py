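"""Statistical inference for mate-choice hypotheses.

The analysis chain mirrors the standard design of MHC mate-choice field
studies:

1. a Pearson correlation screen that removes one member of every
   significantly correlated pair of explanatory variables;
2. a logistic mixed model (logit link, binomial errors) of mate-pair
   formation, where within each mating site the dominant male scores 1
   and the subordinate males 0, with crossed random intercepts for
   sampling year, mating site and male identity;
3. a Pearson chi-square test comparing allele distributions between
   dominant and subordinate males ("good gene" hypothesis), with
   synonymous alleles collapsed to protein classes;
4. a Monte Carlo randomization test comparing the mean pairwise MHC
   dissimilarity of real parent pairs against pairings reshuffled among
   the adult candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from matechoice.errors import InsufficientDataError, MateChoiceError, ValidationError
from matechoice.glmm import GlmmFit, fit_logistic_mixed
from matechoice.metrics import landry_compatibility

log = logging.getLogger(__name__)

DOMINANT = "dominant"
SUBORDINATE = "subordinate"


@dataclass(frozen=True)
class MatingSite:
    """One estrous female with 1-6 competing males, exactly one of whom
    is dominant (wins access to the female)."""

    site_id: str
    year: int
    female: str
    males: tuple[tuple[str, str], ...]  # (male id, status)

    def __post_init__(self):
        statuses = [s for _, s in self.males]
        problems = []
        if not 1 <= len(self.males) <= 6:
            problems.append(f"{len(self.males)} males (expected 1-6)")
        if statuses.count(DOMINANT) != 1:
            problems.append(f"{statuses.count(DOMINANT)} dominant males (expected 1)")
        bad = set(statuses) - {DOMINANT, SUBORDINATE}
        if bad:
            problems.append(f"unknown status {sorted(bad)}")
        if len({m for m, _ in self.males}) != len(self.males):
            problems.append("duplicate male ids")
        if problems:
            raise ValidationError(
                [f"site {self.site_id}: {p}" for p in problems]
            )

    @property
    def dominant_male(self) -> str:
        return next(m for m, s in self.males if s == DOMINANT)


@dataclass(frozen=True)
class DesignRow:
    """One candidate (female, male) pairing within a mating site;
    response is 1 for the dominant male."""

    response: int
    year: int
    site_id: str
    female_id: str
    male_id: str
    explanatory: dict[str, float]


# ---------------------------------------------------------------------------
# Correlation screen


def correlation_screen(
    table: pd.DataFrame,
    alpha: float = 0.05,
    priority: list[str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Pairwise Pearson screen with greedy priority-ordered pruning.

    For every pair of columns, Pearson r and its two-sided p-value
    (t distribution, df = n - 2) are computed on pairwise-complete rows.
    Columns are ranked by ``priority`` (unlisted columns follow in table
    order); scanning pairs in rank order, whenever both members of a
    significant pair (p < alpha) are still retained the lower-priority
    member is dropped. Constant columns are reported as inapplicable and
    never cause a drop.

    Returns (retained column names in original order, report frame with
    columns col_a/col_b/n/r/p/applicable/dropped).
    """
    cols = list(table.columns)
    if len(cols) < 2:
        raise InsufficientDataError("correlation screen needs >= 2 columns")
    if len(table.dropna()) < 3:
        raise InsufficientDataError("correlation screen needs >= 3 complete rows")
    priority = priority or []
    rank = {c: (priority.index(c) if c in priority else len(priority) + i)
            for i, c in enumerate(cols)}
    ordered = sorted(cols, key=lambda c: rank[c])

    retained = set(cols)
    records = []
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            sub = table[[a, b]].dropna()
            n = len(sub)
            applicable = (
                n >= 3
                and sub[a].nunique() > 1
                and sub[b].nunique() > 1
            )
            if applicable:
                r, p = stats.pearsonr(sub[a], sub[b])
                r, p = float(r), float(p)
            else:
                r, p = np.nan, np.nan
            dropped = None
            if applicable and p < alpha and a in retained and b in retained:
                dropped = b  # lower priority by construction
                retained.discard(b)
            records.append(
                {
                    "col_a": a,
                    "col_b": b,
                    "n": n,
                    "r": r,
                    "p": p,
                    "applicable": applicable,
                    "dropped": dropped,
                }
            )
    report = pd.DataFrame(records)
    return [c for c in cols if c in retained], report


# ---------------------------------------------------------------------------
# Design construction


def build_design(
    sites: list[MatingSite],
    individual_table: pd.DataFrame,
    pair_table: pd.DataFrame,
    variables: list[str] | None = None,
    drop_incomplete: bool = True,
) -> pd.DataFrame:
    """One row per (female, candidate male) pairing within each site.

    Male-level variables come from ``individual_table`` (indexed by
    individual id), pair-level variables from ``pair_table`` (columns
    female/male + variables). With ``drop_incomplete``, rows missing any
    requested variable are removed and the count logged; the remaining
    listwise-complete frame feeds the mixed model.
    """
    pair_idx = pair_table.set_index(["female", "male"])
    rows = []
    for site in sites:
        for male, status in site.males:
            if male not in individual_table.index:
                raise KeyError(f"male {male!r} absent from individual metrics")
            row = {
                "response": int(status == DOMINANT),
                "year": site.year,
                "site_id": site.site_id,
                "female_id": site.female,
                "male_id": male,
            }
            row.update(individual_table.loc[male].to_dict())
            if (site.female, male) in pair_idx.index:
                row.update(pair_idx.loc[(site.female, male)].to_dict())
            rows.append(row)
    df = pd.DataFrame(rows)
    if variables is None:
        variables = [
            c for c in df.columns
            if c not in ("response", "year", "site_id", "female_id", "male_id")
        ]
    missing_cols = [v for v in variables if v not in df.columns]
    if missing_cols:
        raise KeyError(f"variables not found: {missing_cols}")
    keep = ["response", "year", "site_id", "female_id", "male_id"] + variables
    df = df[keep]
    if drop_incomplete:
        complete = df.dropna(subset=variables)
        n_dropped = len(df) - len(complete)
        if n_dropped:
            log.info(
                "build_design: dropped %d of %d rows with missing variables",
                n_dropped, len(df),
            )
        df = complete.reset_index(drop=True)
    return df


def fit_mate_choice_glmm(
    design: pd.DataFrame,
    fixed: list[str],
    random: list[str] = ("year", "site", "male"),
    fix_sds: dict[str, float] | None = None,
    standardize: bool = False,
) -> GlmmFit:
    """Fit the mate-pair formation model on a design frame.

    ``random`` factors are drawn from {"year", "site", "male",
    "female"}; each contributes a crossed random intercept. Constant
    fixed-effect columns are dropped (recorded on the fit) -- this is
    what happens to e.g. near-monomorphic-locus heterosis at small n.
    With ``standardize`` the covariates are z-scored before fitting.
    """
    col_map = {
        "year": "year",
        "site": "site_id",
        "male": "male_id",
        "female": "female_id",
    }
    messages = []
    usable = []
    for v in fixed:
        if design[v].nunique() <= 1:
            messages.append(f"fixed effect {v!r} is constant; dropped (inapplicable)")
        else:
            usable.append(v)
    if not usable:
        raise InsufficientDataError("no non-constant fixed effects")
    Xdf = design[usable].astype(float)
    if standardize:
        Xdf = (Xdf - Xdf.mean()) / Xdf.std(ddof=0)
    X = np.column_stack([np.ones(len(design)), Xdf.to_numpy()])
    terms = ["(Intercept)"] + usable
    groups = {}
    for r in random:
        if r not in col_map:
            raise MateChoiceError(f"unknown random factor {r!r}")
        groups[r] = design[col_map[r]].to_numpy()
    fit = fit_logistic_mixed(
        design["response"].to_numpy(), X, terms, groups, fix_sds=fix_sds
    )
    fit.messages = messages + fit.messages
    return fit


# ---------------------------------------------------------------------------
# Good-gene chi-square test


@dataclass
class GoodGeneResult:
    chi2: float
    df: int
    p_value: float
    table: pd.DataFrame  # classes x {dominant, subordinate} counts
    low_expected: bool
    collapsed: dict[str, str]  # allele -> class label actually used


def good_gene_test(
    counts_dominant: dict[str, int],
    counts_subordinate: dict[str, int],
    collapse: dict[str, str] | None = None,
) -> GoodGeneResult:
    """Pearson chi-square on the dominant-vs-subordinate allele table.

    ``collapse`` maps allele names to class labels (synonymous alleles
    share a label and are summed before testing). Classes with zero
    total count are dropped; df = K - 1 for K remaining classes; no
    continuity correction. A flag marks expected counts below 5.
    """
    collapse = collapse or {}
    alleles = sorted(set(counts_dominant) | set(counts_subordinate))
    if not alleles:
        raise InsufficientDataError("empty allele count table")
    used = {a: collapse.get(a, a) for a in alleles}
    classes = sorted(set(used.values()))
    dom = {c: 0 for c in classes}
    sub = {c: 0 for c in classes}
    for a in alleles:
        dom[used[a]] += counts_dominant.get(a, 0)
        sub[used[a]] += counts_subordinate.get(a, 0)
    classes = [c for c in classes if dom[c] + sub[c] > 0]
    if not classes:
        raise InsufficientDataError("all classes have zero count")
    obs = np.array([[dom[c] for c in classes], [sub[c] for c in classes]], dtype=float)
    if obs.sum(axis=1).min() <= 0:
        raise InsufficientDataError("a status margin is empty after collapsing")
    if len(classes) == 1:
        chi2, p, df, expected = 0.0, 1.0, 0, obs
    else:
        chi2, p, df, expected = stats.chi2_contingency(obs, correction=False)
    table = pd.DataFrame(
        obs.T, index=classes, columns=["dominant", "subordinate"]
    )
    return GoodGeneResult(
        chi2=float(chi2),
        df=int(df),
        p_value=float(p),
        table=table,
        low_expected=bool(np.min(expected) < 5),
        collapsed=used,
    )


# ---------------------------------------------------------------------------
# Monte Carlo parent-pair randomization


@dataclass
class PermutationResult:
    observed_mean: float
    null_means: np.ndarray
    p_value: float
    n_real_pairs: int
    n_candidates: int
    metric_name: str
    seed: int
    tail: str

    def to_summary(self) -> dict:
        return {
            "observed_mean": self.observed_mean,
            "null_mean": float(np.mean(self.null_means)),
            "p_value": self.p_value,
            "n_real_pairs": self.n_real_pairs,
            "n_candidates": self.n_candidates,
            "n_shuffles": int(len(self.null_means)),
            "metric": self.metric_name,
            "tail": self.tail,
        }


def parent_pair_randomization(
    pairs: list[tuple[str, str]],
    females: list[str],
    males: list[str],
    metric,
    n_shuffles: int = 10_000,
    seed: int = 0,
    tail: str = "two-sided",
    metric_name: str = "metric",
) -> PermutationResult:
    """Monte Carlo test of non-random pairing among parent pairs.

    The observed statistic is the mean of ``metric(female, male)`` over
    the real (mother, father) pairs. Each shuffle draws len(pairs)
    pairings by sampling females and males without replacement from the
    candidate pools (cubs excluded by the caller; entries may repeat to
    weight multi-pair parents). The p-value uses the add-one rule
    p = (k + 1) / (n_shuffles + 1), counting null means at least as
    extreme as the observed under the chosen tail; two-sided extremeness
    is distance from the null median.

    Individuals for whom the metric is undefined (missing genotypes)
    are removed from the pools, and real pairs involving them are
    excluded from the observed mean; both removals are logged.
    """
    if n_shuffles < 1:
        raise InsufficientDataError("n_shuffles must be >= 1")
    if tail not in ("two-sided", "lower", "upper"):
        raise MateChoiceError(f"unknown tail {tail!r}")

    # Pre-screen pool members: drop anyone whose metric fails everywhere.
    def usable(ids, partners, is_female):
        good, bad = [], []
        for i in ids:
            ok = False
            for j in partners:
                try:
                    v = metric(i, j) if is_female else metric(j, i)
                except MateChoiceError:
                    continue
                if v is not None and np.isfinite(v):
                    ok = True
                    break
            (good if ok else bad).append(i)
        return good, bad

    females_ok, f_bad = usable(list(females), list(males), True)
    males_ok, m_bad = usable(list(males), females_ok, False)
    if f_bad or m_bad:
        log.info(
            "permutation: excluded %d females, %d males with undefined metric",
            len(set(f_bad)), len(set(m_bad)),
        )
    if not females_ok or not males_ok:
        raise InsufficientDataError("candidate pool empty after exclusions")

    observed_vals = []
    for mo, fa in pairs:
        try:
            v = metric(mo, fa)
        except MateChoiceError:
            v = None
        if v is None or not np.isfinite(v):
            log.info("permutation: real pair (%s, %s) excluded", mo, fa)
            continue
        observed_vals.append(v)
    if not observed_vals:
        raise InsufficientDataError("no real pair with a defined metric")
    k_pairs = len(observed_vals)
    if k_pairs > len(females_ok) or k_pairs > len(males_ok):
        raise InsufficientDataError(
            "candidate pools smaller than the number of real pairs"
        )
    observed = float(np.mean(observed_vals))

    # Metric matrix over the pools (cached by id, so duplicated pool
    # entries cost nothing extra).
    uf = list(dict.fromkeys(females_ok))
    um = list(dict.fromkeys(males_ok))
    mat = np.empty((len(uf), len(um)))
    for i, f in enumerate(uf):
        for j, m in enumerate(um):
            try:
                v = metric(f, m)
            except MateChoiceError:
                v = np.nan
            mat[i, j] = np.nan if v is None else v
    fi = np.array([uf.index(f) for f in females_ok])
    mi = np.array([um.index(m) for m in males_ok])

    rng = np.random.default_rng(seed)
    perm_f = rng.permuted(
        np.tile(np.arange(len(females_ok)), (n_shuffles, 1)), axis=1
    )[:, :k_pairs]
    perm_m = rng.permuted(
        np.tile(np.arange(len(males_ok)), (n_shuffles, 1)), axis=1
    )[:, :k_pairs]
    vals = mat[fi[perm_f], mi[perm_m]]
    null_means = np.nanmean(vals, axis=1)
    if not np.all(np.isfinite(null_means)):
        raise MateChoiceError("non-finite null means; metric failed inside pools")

    eps = 1e-12
    if tail == "lower":
        k = int(np.sum(null_means <= observed + eps))
    elif tail == "upper":
        k = int(np.sum(null_means >= observed - eps))
    else:
        med = float(np.median(null_means))
        k = int(np.sum(np.abs(null_means - med) >= abs(observed - med) - eps))
    p = (k + 1) / (n_shuffles + 1)
    return PermutationResult(
        observed_mean=observed,
        null_means=null_means,
        p_value=float(p),
        n_real_pairs=k_pairs,
        n_candidates=len(set(females_ok) | set(males_ok)),
        metric_name=metric_name,
        seed=seed,
        tail=tail,
    )


# ---------------------------------------------------------------------------
# Full pipeline


@dataclass
class AnalysisConfig:
    """Knobs of the full analysis; defaults follow the field-standard
    choices documented in docs/methods.md."""

    alpha: float = 0.05
    heterosis_level: str = "allele"
    random_factors: tuple[str, ...] = ("year", "site", "male")
    standardize: bool = False
    n_shuffles: int = 10_000
    permutation_tail: str = "two-sided"
    permutation_locus: str | None = None  # default: first locus
    wetton_as_dissimilarity: bool = False
    priority: tuple[str, ...] = ()  # extra high-priority screen columns


@dataclass
class AnalysisReport:
    """Serializable result bundle of :func:`run_full_analysis`."""

    diversity_screen: pd.DataFrame
    diversity_retained: list[str]
    compatibility_screen: pd.DataFrame
    compatibility_retained: list[str]
    glmm: GlmmFit
    glmm_variables: list[str]
    good_gene: dict[str, GoodGeneResult]
    permutation: dict[str, PermutationResult]
    n_design_rows: int
    n_sites: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_design_rows": self.n_design_rows,
            "n_sites": self.n_sites,
            "diversity_screen": self.diversity_screen.to_dict(orient="records"),
            "diversity_retained": self.diversity_retained,
            "compatibility_screen": self.compatibility_screen.to_dict(
                orient="records"
            ),
            "compatibility_retained": self.compatibility_retained,
            "glmm_variables": self.glmm_variables,
            "glmm": {
                "fixed_effects": self.glmm.fixed_effects.to_dict(orient="records"),
                "random_variances": self.glmm.random_variances,
                "loglik": self.glmm.loglik,
                "converged": self.glmm.converged,
                "n_rows": self.glmm.n_rows,
                "n_groups": self.glmm.n_groups,
                "messages": self.glmm.messages,
            },
            "good_gene": {
                locus: {
                    "chi2": r.chi2,
                    "df": r.df,
                    "p_value": r.p_value,
                    "low_expected": r.low_expected,
                    "table": r.table.reset_index(names="class").to_dict(
                        orient="records"
                    ),
                    "collapsed": r.collapsed,
                }
                for locus, r in self.good_gene.items()
            },
            "permutation": {
                name: r.to_summary() for name, r in self.permutation.items()
            },
        }


def _dominance_allele_counts(
    sites: list[MatingSite],
    locus: str,
    mhc_genotypes,
) -> tuple[dict[str, int], dict[str, int]]:
    """Allele-copy counts among dominant vs subordinate males; each
    (site, male) participation contributes two copies."""
    dom: dict[str, int] = {}
    sub: dict[str, int] = {}
    for site in sites:
        for male, status in site.males:
            g = mhc_genotypes.get((male, locus))
            if g is None or g.missing:
                continue
            target = dom if status == DOMINANT else sub
            for a in g.alleles():
                target[a] = target.get(a, 0) + 1
    return dom, sub


def run_full_analysis(dataset, config: AnalysisConfig | None = None, seed: int = 0):
    """Run screen -> mixed model -> good-gene tests -> randomization.

    ``dataset`` is a :class:`matechoice.dataio.Dataset`. Deterministic
    given the dataset and seed.
    """
    from matechoice.metrics import (
        AlleleFrequencyTable,
        individual_metric_table,
        pair_metric_table,
    )

    config = config or AnalysisConfig()
    loci = list(dataset.dbs)
    freqs = dataset.allele_frequencies()

    site_males = sorted({m for s in dataset.sites for m, _ in s.males})
    ind_table = individual_metric_table(
        site_males, loci, dataset.dbs, dataset.mhc_genotypes,
        dataset.microsat_genotypes, freqs,
        heterosis_level=config.heterosis_level,
    )
    site_pairs = sorted({(s.female, m) for s in dataset.sites for m, _ in s.males})
    pair_table = pair_metric_table(
        site_pairs, loci, dataset.dbs, dataset.mhc_genotypes,
        dataset.microsat_genotypes, freqs,
    )
    if config.wetton_as_dissimilarity:
        for locus in loci:
            pair_table[f"{locus}_compatibility2"] = (
                1.0 - pair_table[f"{locus}_compatibility2"]
            )

    # Screen 1: male diversity measures (SH, IR, per-locus diversity).
    div_cols = ["SH", "IR"] + [
        f"{locus}_{kind}" for locus in loci for kind in ("diversity", "ABS_diversity")
    ]
    div_priority = list(config.priority) + ["SH"] + [
        f"{locus}_diversity" for locus in loci
    ] + [f"{locus}_ABS_diversity" for locus in loci] + ["IR"]
    div_retained, div_report = correlation_screen(
        ind_table[div_cols], alpha=config.alpha, priority=div_priority
    )

    # Screen 2: pairwise compatibility measures (+ relatedness).
    comp_cols = ["relatedness"] + [
        f"{locus}_{kind}"
        for locus in loci
        for kind in ("compatibility1", "ABS_compatibility1", "compatibility2")
    ]
    comp_priority = list(config.priority) + ["relatedness"] + [
        f"{locus}_compatibility1" for locus in loci
    ] + [f"{locus}_ABS_compatibility1" for locus in loci] + [
        f"{locus}_compatibility2" for locus in loci
    ]
    comp_retained, comp_report = correlation_screen(
        pair_table[comp_cols], alpha=config.alpha, priority=comp_priority
    )

    heterosis_cols = [f"{locus}_heterosis" for locus in loci]
    glmm_vars = [
        c for c in (heterosis_cols + div_retained + comp_retained)
    ]
    design = build_design(
        dataset.sites, ind_table, pair_table, variables=glmm_vars
    )
    glmm_fit = fit_mate_choice_glmm(
        design, glmm_vars, random=list(config.random_factors),
        standardize=config.standardize,
    )

    good_gene = {}
    for locus in loci:
        dom, sub = _dominance_allele_counts(
            dataset.sites, locus, dataset.mhc_genotypes
        )
        if not dom or not sub:
            continue
        collapse = {
            name: f"protein_{a.protein_class}"
            for name, a in dataset.dbs[locus].alleles.items()
        }
        good_gene[locus] = good_gene_test(dom, sub, collapse)

    permutation = {}
    if dataset.parent_pairs:
        perm_locus = config.permutation_locus or loci[0]
        db = dataset.dbs[perm_locus]
        females, males = dataset.parent_candidate_pools()

        def make_metric(use_mask):
            def metric(f, m):
                gf = dataset.mhc_genotypes.get((f, perm_locus))
                gm = dataset.mhc_genotypes.get((m, perm_locus))
                if gf is None or gm is None or gf.missing or gm.missing:
                    return None
                return landry_compatibility(gf, gm, db, use_mask=use_mask)
            return metric

        permutation["all_sites"] = parent_pair_randomization(
            dataset.parent_pairs, females, males, make_metric(False),
            n_shuffles=config.n_shuffles, seed=seed,
            tail=config.permutation_tail,
            metric_name=f"{perm_locus}_compatibility1",
        )
        if db.mask is not None:
            permutation["abs"] = parent_pair_randomization(
                dataset.parent_pairs, females, males, make_metric(True),
                n_shuffles=config.n_shuffles, seed=seed + 1,
                tail=config.permutation_tail,
                metric_name=f"{perm_locus}_ABS_compatibility1",
            )

    return AnalysisReport(
        diversity_screen=div_report,
        diversity_retained=div_retained,
        compatibility_screen=comp_report,
        compatibility_retained=comp_retained,
        glmm=glmm_fit,
        glmm_variables=glmm_vars,
        good_gene=good_gene,
        permutation=permutation,
        n_design_rows=len(design),
        n_sites=len(dataset.sites),
        seed=seed,
    )
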
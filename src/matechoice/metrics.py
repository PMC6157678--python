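"""Individual and pairwise genetic metrics.

MHC-side variables (per locus):

* heterosis indicator -- is the genotype heterozygous (at the allele or
  protein level);
* diversity -- amino-acid Hamming distance between an individual's two
  alleles, optionally restricted to antigen-binding sites (ABS);
* compatibility1 (Landry) -- mean of the four cross-pair amino-acid
  distances between one individual's alleles {C, c} and the partner's
  {D, d}: (P_CD + P_Cd + P_cD + P_cd) / 4;
* compatibility2 (Wetton band-sharing D) -- 2*Fab / (Fa + Fb) over the
  distinct protein classes the two individuals carry.

Microsatellite-side variables:

* SH, standardized individual heterozygosity -- observed heterozygous
  proportion divided by the mean expected heterozygosity of the typed
  loci;
* IR, internal relatedness -- (2H - sum f) / (2N - sum f), an
  allele-frequency-weighted homozygosity in (-inf, 1];
* pairwise relatedness -- symmetrized Queller-Goodnight moment
  estimator, loci pooled by summing numerators and denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from matechoice.alleles import LocusAlleleDb, aa_distance
from matechoice.errors import (
    FrequencyTableError,
    MateChoiceError,
    MissingDataError,
)

MicrosatCall = tuple[int, int]


@dataclass(frozen=True)
class MhcGenotype:
    """One individual's genotype at one MHC locus.

    ``allele1``/``allele2`` form an unordered pair (homozygotes repeat
    the name); both are ``None`` when ``missing``.
    """

    individual: str
    locus: str
    allele1: str | None
    allele2: str | None
    missing: bool = False

    def __post_init__(self):
        if self.missing and (self.allele1 or self.allele2):
            raise MateChoiceError("missing genotype must not carry allele names")
        if not self.missing and not (self.allele1 and self.allele2):
            raise MateChoiceError("non-missing genotype needs two allele names")

    def alleles(self) -> tuple[str, str]:
        if self.missing:
            raise MissingDataError(
                f"{self.individual}: missing genotype at {self.locus}"
            )
        return self.allele1, self.allele2


@dataclass
class MicrosatGenotype:
    """Per-locus unordered integer allele pairs; ``None`` = untyped."""

    individual: str
    calls: dict[str, MicrosatCall | None] = field(default_factory=dict)

    def typed_loci(self) -> list[str]:
        return [k for k, v in self.calls.items() if v is not None]


class AlleleFrequencyTable:
    """Per-locus relative allele frequencies (microsatellite labels are
    integer fragment sizes)."""

    def __init__(self, freqs: dict[str, dict[int, float]]):
        for locus, table in freqs.items():
            tot = sum(table.values())
            if not np.isclose(tot, 1.0, atol=1e-9):
                raise FrequencyTableError(
                    f"locus {locus}: frequencies sum to {tot}, not 1"
                )
            if any(f <= 0 for f in table.values()):
                raise FrequencyTableError(f"locus {locus}: non-positive frequency")
        self._freqs = freqs

    def freq(self, locus: str, allele: int) -> float:
        try:
            return self._freqs[locus][allele]
        except KeyError:
            raise FrequencyTableError(
                f"allele {allele} at locus {locus} absent from frequency table"
            ) from None

    def expected_heterozygosity(self, locus: str) -> float:
        table = self._freqs[locus]
        return 1.0 - sum(f * f for f in table.values())

    def loci(self) -> list[str]:
        return list(self._freqs)

    @classmethod
    def from_genotypes(cls, genotypes: list[MicrosatGenotype]) -> "AlleleFrequencyTable":
        """Empirical frequencies from observed allele copies."""
        counts: dict[str, dict[int, int]] = {}
        for g in genotypes:
            for locus, call in g.calls.items():
                if call is None:
                    continue
                tab = counts.setdefault(locus, {})
                for a in call:
                    tab[a] = tab.get(a, 0) + 1
        freqs = {
            locus: {a: c / sum(tab.values()) for a, c in tab.items()}
            for locus, tab in counts.items()
        }
        if not freqs:
            raise MissingDataError("no typed microsatellite genotypes")
        return cls(freqs)


@dataclass
class PairMetrics:
    """Pairwise explanatory variables for one (female, male) pair.

    Per-locus dicts map locus -> value, with ``None`` where either
    genotype is missing (listwise exclusion happens downstream).
    """

    female: str
    male: str
    compatibility1: dict[str, float | None] = field(default_factory=dict)
    abs_compatibility1: dict[str, float | None] = field(default_factory=dict)
    compatibility2: dict[str, float | None] = field(default_factory=dict)
    relatedness: float | None = None


# ---------------------------------------------------------------------------
# MHC metrics


def heterosis_indicator(
    g: MhcGenotype,
    db: LocusAlleleDb | None = None,
    level: str = "allele",
) -> int:
    """1 if the genotype is heterozygous at the chosen level, else 0.

    ``level="allele"`` compares allele names (nucleotide-distinct);
    ``level="protein"`` compares protein classes, so a synonymous pair
    counts as homozygous and requires ``db`` with classes assigned.
    """
    a1, a2 = g.alleles()
    if level == "allele":
        return int(a1 != a2)
    if level == "protein":
        if db is None:
            raise MateChoiceError("protein-level heterosis needs the allele db")
        return int(db.get(a1).protein_class != db.get(a2).protein_class)
    raise MateChoiceError(f"unknown heterosis level {level!r}")


def mhc_diversity(g: MhcGenotype, db: LocusAlleleDb, use_mask: bool = False) -> int:
    """Amino-acid distance between an individual's two alleles."""
    a1, a2 = g.alleles()
    mask = None
    if use_mask:
        if db.mask is None:
            raise MateChoiceError(f"locus {db.locus} has no ABS mask")
        mask = db.mask
    return aa_distance(db.get(a1).aa_seq, db.get(a2).aa_seq, mask)


def landry_compatibility(
    gf: MhcGenotype,
    gm: MhcGenotype,
    db: LocusAlleleDb,
    use_mask: bool = False,
) -> float:
    """Mean cross-pair amino-acid distance between two individuals.

    With female alleles {C, c} and male alleles {D, d} this is
    (P_CD + P_Cd + P_cD + P_cd) / 4; homozygotes contribute their allele
    twice. Symmetric in the two individuals.
    """
    if gf.locus != gm.locus:
        raise MateChoiceError(
            f"locus mismatch: {gf.locus} vs {gm.locus}"
        )
    mask = None
    if use_mask:
        if db.mask is None:
            raise MateChoiceError(f"locus {db.locus} has no ABS mask")
        mask = db.mask
    f_seqs = [db.get(a).aa_seq for a in gf.alleles()]
    m_seqs = [db.get(a).aa_seq for a in gm.alleles()]
    total = sum(aa_distance(fa, ma, mask) for fa in f_seqs for ma in m_seqs)
    return total / 4.0


def wetton_sharing(gf: MhcGenotype, gm: MhcGenotype, db: LocusAlleleDb) -> float:
    """Band-sharing similarity D = 2*Fab / (Fa + Fb) on protein classes.

    Fa and Fb are the numbers of distinct protein classes each
    individual carries at the locus (1 or 2); Fab is the number shared.
    """
    if gf.locus != gm.locus:
        raise MateChoiceError(f"locus mismatch: {gf.locus} vs {gm.locus}")
    fa = {db.get(a).protein_class for a in gf.alleles()}
    fb = {db.get(a).protein_class for a in gm.alleles()}
    if None in fa or None in fb:
        raise MateChoiceError(f"locus {db.locus}: protein classes not assigned")
    return 2.0 * len(fa & fb) / (len(fa) + len(fb))


# ---------------------------------------------------------------------------
# Microsatellite metrics


def standardized_heterozygosity(
    g: MicrosatGenotype, freqs: AlleleFrequencyTable
) -> float:
    """SH: heterozygous proportion of typed loci, standardized by the
    mean expected heterozygosity (1 - sum f^2) of those same loci."""
    typed = g.typed_loci()
    if not typed:
        raise MissingDataError(f"{g.individual}: no typed microsatellite loci")
    obs = np.mean([g.calls[k][0] != g.calls[k][1] for k in typed])
    exp = np.mean([freqs.expected_heterozygosity(k) for k in typed])
    if exp <= 0:
        raise FrequencyTableError("mean expected heterozygosity is zero")
    return float(obs / exp)


def internal_relatedness(g: MicrosatGenotype, freqs: AlleleFrequencyTable) -> float:
    """IR = (2H - sum f_i) / (2N - sum f_i).

    H = number of homozygous typed loci, N = typed loci, and sum f_i
    runs over the population frequencies of all 2N carried allele
    copies. Equals 1 iff fully homozygous.
    """
    typed = g.typed_loci()
    if not typed:
        raise MissingDataError(f"{g.individual}: no typed microsatellite loci")
    n = len(typed)
    h = sum(g.calls[k][0] == g.calls[k][1] for k in typed)
    sf = sum(freqs.freq(k, a) for k in typed for a in g.calls[k])
    denom = 2 * n - sf
    if denom == 0:
        raise FrequencyTableError("IR denominator is zero")
    return float((2 * h - sf) / denom)


def _qg_one_direction(
    focal: MicrosatGenotype,
    other: MicrosatGenotype,
    freqs: AlleleFrequencyTable,
    loci: list[str],
) -> tuple[float, float]:
    """Queller-Goodnight numerator/denominator sums with `focal` as the
    reference individual, pooled over loci."""
    num = 0.0
    den = 0.0
    for k in loci:
        x1, x2 = focal.calls[k]
        y1, y2 = other.calls[k]
        share = 0.5 * (
            (x1 == y1) + (x1 == y2) + (x2 == y1) + (x2 == y2)
        )
        pf = freqs.freq(k, x1) + freqs.freq(k, x2)
        num += share - pf
        den += 1 + (x1 == x2) - pf
    return num, den


def pairwise_relatedness(
    ga: MicrosatGenotype,
    gb: MicrosatGenotype,
    freqs: AlleleFrequencyTable,
) -> float:
    """Symmetrized Queller-Goodnight relatedness.

    Computed in both reference-individual directions with loci pooled
    (numerators and denominators summed across loci), then averaged.
    Expectation is ~0 for unrelated pairs and ~0.5 for parent-offspring
    pairs under the generating frequencies.
    """
    loci = sorted(set(ga.typed_loci()) & set(gb.typed_loci()))
    if not loci:
        raise MissingDataError(
            f"no loci typed in both {ga.individual} and {gb.individual}"
        )
    num_a, den_a = _qg_one_direction(ga, gb, freqs, loci)
    num_b, den_b = _qg_one_direction(gb, ga, freqs, loci)
    ratios = [n / d for n, d in ((num_a, den_a), (num_b, den_b)) if d != 0]
    if not ratios:
        raise MissingDataError("relatedness undefined: zero denominators")
    return float(np.mean(ratios))


# ---------------------------------------------------------------------------
# Assembly


def build_pair_metrics(
    female: str,
    male: str,
    loci: list[str],
    dbs: dict[str, LocusAlleleDb],
    mhc_genotypes: dict[tuple[str, str], MhcGenotype],
    microsat_genotypes: dict[str, MicrosatGenotype] | None = None,
    freqs: AlleleFrequencyTable | None = None,
) -> PairMetrics:
    """Assemble the pairwise variable row for one (female, male) pair.

    ``mhc_genotypes`` maps (individual, locus) to a genotype. Loci with
    a missing genotype on either side yield ``None`` fields.
    """
    pm = PairMetrics(female=female, male=male)
    for locus in loci:
        try:
            gf = mhc_genotypes[(female, locus)]
            gm = mhc_genotypes[(male, locus)]
        except KeyError as e:
            raise KeyError(f"unknown individual/locus {e.args[0]}") from None
        if gf.missing or gm.missing:
            pm.compatibility1[locus] = None
            pm.abs_compatibility1[locus] = None
            pm.compatibility2[locus] = None
            continue
        db = dbs[locus]
        pm.compatibility1[locus] = landry_compatibility(gf, gm, db, use_mask=False)
        pm.abs_compatibility1[locus] = (
            landry_compatibility(gf, gm, db, use_mask=True)
            if db.mask is not None
            else None
        )
        pm.compatibility2[locus] = wetton_sharing(gf, gm, db)
    if microsat_genotypes is not None and freqs is not None:
        try:
            pm.relatedness = pairwise_relatedness(
                microsat_genotypes[female], microsat_genotypes[male], freqs
            )
        except MissingDataError:
            pm.relatedness = None
    return pm


def individual_metric_table(
    individuals: list[str],
    loci: list[str],
    dbs: dict[str, LocusAlleleDb],
    mhc_genotypes: dict[tuple[str, str], MhcGenotype],
    microsat_genotypes: dict[str, MicrosatGenotype],
    freqs: AlleleFrequencyTable,
    heterosis_level: str = "allele",
) -> pd.DataFrame:
    """Per-individual variables: SH, IR and per-locus heterosis /
    diversity / ABS_diversity. Missing genotypes give NaN."""
    rows = []
    for ind in individuals:
        row: dict[str, float] = {"individual": ind}
        ms = microsat_genotypes.get(ind)
        if ms is not None and ms.typed_loci():
            row["SH"] = standardized_heterozygosity(ms, freqs)
            row["IR"] = internal_relatedness(ms, freqs)
        else:
            row["SH"] = np.nan
            row["IR"] = np.nan
        for locus in loci:
            g = mhc_genotypes.get((ind, locus))
            db = dbs[locus]
            if g is None or g.missing:
                row[f"{locus}_heterosis"] = np.nan
                row[f"{locus}_diversity"] = np.nan
                row[f"{locus}_ABS_diversity"] = np.nan
                continue
            row[f"{locus}_heterosis"] = heterosis_indicator(
                g, db, level=heterosis_level
            )
            row[f"{locus}_diversity"] = mhc_diversity(g, db, use_mask=False)
            row[f"{locus}_ABS_diversity"] = (
                mhc_diversity(g, db, use_mask=True) if db.mask is not None else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("individual")


def pair_metric_table(
    pairs: list[tuple[str, str]],
    loci: list[str],
    dbs: dict[str, LocusAlleleDb],
    mhc_genotypes: dict[tuple[str, str], MhcGenotype],
    microsat_genotypes: dict[str, MicrosatGenotype],
    freqs: AlleleFrequencyTable,
) -> pd.DataFrame:
    """Per-pair variables: relatedness and per-locus compatibility1 /
    ABS_compatibility1 / compatibility2. Missing genotypes give NaN."""
    rows = []
    for female, male in pairs:
        pm = build_pair_metrics(
            female, male, loci, dbs, mhc_genotypes, microsat_genotypes, freqs
        )
        row: dict[str, float] = {"female": female, "male": male}
        row["relatedness"] = np.nan if pm.relatedness is None else pm.relatedness
        for locus in loci:
            for key, store in [
                ("compatibility1", pm.compatibility1),
                ("ABS_compatibility1", pm.abs_compatibility1),
                ("compatibility2", pm.compatibility2),
            ]:
                v = store[locus]
                row[f"{locus}_{key}"] = np.nan if v is None else v
        rows.append(row)
    return pd.DataFrame(rows)
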
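"""Dataset container, file I/O and validation.

Canonical on-disk layout is plain text: one FASTA per MHC locus
(record ids ``Locus*AlleleName``), tab-delimited genotype and
observation tables with header rows, and a YAML config naming the files
and per-locus settings (frame offset, 1-based ABS columns):

* ``individuals.tsv``: individual, sex (F/M) -- adults only;
* ``mhc_genotypes.tsv``: individual, locus, allele1, allele2
  (empty cells = missing genotype);
* ``microsat_genotypes.tsv``: individual, locus, a1, a2 (integer
  fragment sizes; empty = untyped);
* ``sites.tsv``: site, year, female, male, status -- one row per
  candidate male, status in {dominant, subordinate};
* ``parent_pairs.tsv``: mother, father[, cub].

Validation is total: loading collects every integrity violation (with
row context) and raises one :class:`ValidationError`, never returning a
partially valid dataset.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from matechoice.alleles import LocusAlleleDb, read_allele_fasta
from matechoice.errors import ValidationError
from matechoice.inference import AnalysisReport, MatingSite
from matechoice.metrics import AlleleFrequencyTable, MhcGenotype, MicrosatGenotype


@dataclass
class Dataset:
    """Validated in-memory dataset for the full analysis."""

    dbs: dict[str, LocusAlleleDb]
    mhc_genotypes: dict[tuple[str, str], MhcGenotype]
    microsat_genotypes: dict[str, MicrosatGenotype]
    sexes: dict[str, str]  # individual -> 'F' | 'M'
    sites: list[MatingSite]
    parent_pairs: list[tuple[str, str]]  # (mother, father)
    provenance: dict = field(default_factory=dict)

    def allele_frequencies(self) -> AlleleFrequencyTable:
        """Microsatellite allele frequencies over all adults on file."""
        return AlleleFrequencyTable.from_genotypes(
            list(self.microsat_genotypes.values())
        )

    def parent_candidate_pools(self) -> tuple[list[str], list[str]]:
        """Female and male shuffle pools for the parent-pair
        randomization: every adult once, with parents of multiple pairs
        repeated to carry their pair multiplicity."""
        females = sorted(i for i, s in self.sexes.items() if s == "F")
        males = sorted(i for i, s in self.sexes.items() if s == "M")
        for pool, idx in ((females, 0), (males, 1)):
            counts: dict[str, int] = {}
            for pair in self.parent_pairs:
                counts[pair[idx]] = counts.get(pair[idx], 0) + 1
            for ind, c in sorted(counts.items()):
                pool.extend([ind] * (c - 1))
        return females, males

    def validate(self) -> list[str]:
        """Return every integrity problem found (empty list = valid)."""
        problems: list[str] = []
        known = set(self.sexes)
        for (ind, locus), g in self.mhc_genotypes.items():
            if locus not in self.dbs:
                problems.append(f"mhc genotype {ind}/{locus}: unknown locus")
                continue
            if g.missing:
                continue
            for a in (g.allele1, g.allele2):
                if a not in self.dbs[locus].alleles:
                    problems.append(
                        f"mhc genotype {ind}/{locus}: unknown allele {a!r}"
                    )
        for site in self.sites:
            if site.female not in known:
                problems.append(f"site {site.site_id}: unknown female {site.female!r}")
            elif self.sexes[site.female] != "F":
                problems.append(
                    f"site {site.site_id}: {site.female!r} is not female"
                )
            for m, _ in site.males:
                if m not in known:
                    problems.append(f"site {site.site_id}: unknown male {m!r}")
                elif self.sexes[m] != "M":
                    problems.append(f"site {site.site_id}: {m!r} is not male")
        for mo, fa in self.parent_pairs:
            if mo not in known:
                problems.append(f"parent pair: unknown mother {mo!r}")
            if fa not in known:
                problems.append(f"parent pair: unknown father {fa!r}")
        dup = {s.site_id for s in self.sites if
               sum(t.site_id == s.site_id for t in self.sites) > 1}
        if dup:
            problems.append(f"duplicate site ids: {sorted(dup)}")
        return problems


def _read_tsv(path: Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as e:  # parse failure with file context
        raise ValidationError([f"{path.name}: cannot parse ({e})"]) from e
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError([f"{path.name}: missing columns {missing}"])
    return df


def load_dataset(config_path: str | Path) -> Dataset:
    """Load and validate a dataset bundle described by a YAML config.

    The config lives in the bundle directory; relative paths resolve
    against it. Raises :class:`ValidationError` carrying every problem
    found if the bundle is malformed.
    """
    config_path = Path(config_path)
    root = config_path.parent
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)

    problems: list[str] = []
    dbs: dict[str, LocusAlleleDb] = {}
    for spec in cfg.get("loci", []):
        name = spec["name"]
        try:
            dbs[name] = read_allele_fasta(
                root / spec["fasta"],
                name,
                frame_offset=int(spec.get("frame_offset", 0)),
                abs_positions=spec.get("abs_positions"),
            )
        except Exception as e:
            problems.append(f"locus {name}: {e}")

    files = cfg.get("files", {})

    ind_df = _read_tsv(root / files.get("individuals", "individuals.tsv"),
                       ["individual", "sex"])
    sexes: dict[str, str] = {}
    for i, row in ind_df.iterrows():
        ind, sex = row["individual"], row["sex"].upper()
        if ind in sexes:
            problems.append(f"individuals.tsv row {i + 2}: duplicate id {ind!r}")
        if sex not in ("F", "M"):
            problems.append(f"individuals.tsv row {i + 2}: bad sex {row['sex']!r}")
        sexes[ind] = sex

    mhc_df = _read_tsv(root / files.get("mhc_genotypes", "mhc_genotypes.tsv"),
                       ["individual", "locus", "allele1", "allele2"])
    mhc: dict[tuple[str, str], MhcGenotype] = {}
    for i, row in mhc_df.iterrows():
        key = (row["individual"], row["locus"])
        if key in mhc:
            problems.append(
                f"mhc_genotypes.tsv row {i + 2}: duplicate genotype for {key}"
            )
            continue
        missing = row["allele1"] == "" or row["allele2"] == ""
        mhc[key] = MhcGenotype(
            individual=key[0], locus=key[1],
            allele1=None if missing else row["allele1"],
            allele2=None if missing else row["allele2"],
            missing=missing,
        )

    ms_df = _read_tsv(root / files.get("microsat_genotypes", "microsat_genotypes.tsv"),
                      ["individual", "locus", "a1", "a2"])
    micro: dict[str, MicrosatGenotype] = {}
    seen_ms = set()
    for i, row in ms_df.iterrows():
        key = (row["individual"], row["locus"])
        if key in seen_ms:
            problems.append(
                f"microsat_genotypes.tsv row {i + 2}: duplicate genotype for {key}"
            )
            continue
        seen_ms.add(key)
        g = micro.setdefault(row["individual"], MicrosatGenotype(row["individual"]))
        if row["a1"] == "" or row["a2"] == "":
            g.calls[row["locus"]] = None
        else:
            try:
                g.calls[row["locus"]] = (int(row["a1"]), int(row["a2"]))
            except ValueError:
                problems.append(
                    f"microsat_genotypes.tsv row {i + 2}: non-integer allele size"
                )

    sites_df = _read_tsv(root / files.get("sites", "sites.tsv"),
                         ["site", "year", "female", "male", "status"])
    sites: list[MatingSite] = []
    for site_id, grp in sites_df.groupby("site", sort=True):
        females = grp["female"].unique()
        years = grp["year"].unique()
        if len(females) > 1:
            problems.append(f"site {site_id}: multiple females {list(females)}")
        if len(years) > 1:
            problems.append(f"site {site_id}: multiple years {list(years)}")
        try:
            sites.append(
                MatingSite(
                    site_id=str(site_id),
                    year=int(years[0]),
                    female=females[0],
                    males=tuple(zip(grp["male"], grp["status"])),
                )
            )
        except (ValidationError, ValueError) as e:
            problems.extend(getattr(e, "problems", [f"site {site_id}: {e}"]))

    pp_df = _read_tsv(root / files.get("parent_pairs", "parent_pairs.tsv"),
                      ["mother", "father"])
    pairs = [(r["mother"], r["father"]) for _, r in pp_df.iterrows()]

    ds = Dataset(
        dbs=dbs,
        mhc_genotypes=mhc,
        microsat_genotypes=micro,
        sexes=sexes,
        sites=sites,
        parent_pairs=pairs,
        provenance={
            "config": str(config_path),
            "config_sha256": hashlib.sha256(config_path.read_bytes()).hexdigest(),
        },
    )
    problems.extend(ds.validate())
    if problems:
        raise ValidationError(problems)
    return ds


# ---------------------------------------------------------------------------
# Writers


def _fmt(v) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_tsv(df: pd.DataFrame, path: Path) -> None:
    """Deterministic TSV: fixed column order, full float precision."""
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, df.columns)) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_report(report: AnalysisReport, out_dir: str | Path) -> list[Path]:
    """Write the analysis report: a JSON mirror plus TSV tables.

    The mixed-model table has exactly the columns term, estimate,
    std_error, z_value, p_value. Output is byte-deterministic for a
    given report.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    p = out / "report.json"
    with open(p, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(p)

    p = out / "glmm_table.tsv"
    write_tsv(
        report.glmm.fixed_effects[
            ["term", "estimate", "std_error", "z_value", "p_value"]
        ],
        p,
    )
    written.append(p)

    for name, df in [
        ("diversity_screen", report.diversity_screen),
        ("compatibility_screen", report.compatibility_screen),
    ]:
        p = out / f"{name}.tsv"
        write_tsv(df, p)
        written.append(p)

    rows = []
    for locus, r in sorted(report.good_gene.items()):
        rows.append(
            {"locus": locus, "chi2": r.chi2, "df": r.df,
             "p_value": r.p_value, "low_expected": r.low_expected}
        )
    if rows:
        p = out / "good_gene.tsv"
        write_tsv(pd.DataFrame(rows), p)
        written.append(p)

    rows = []
    for name, r in sorted(report.permutation.items()):
        rows.append({"variant": name, **r.to_summary()})
    if rows:
        p = out / "permutation.tsv"
        write_tsv(pd.DataFrame(rows), p)
        written.append(p)
    return written


def write_dataset(dataset: Dataset, out_dir: str | Path,
                  extra_config: dict | None = None) -> Path:
    """Write a dataset bundle (FASTAs, TSVs, config.yaml); returns the
    config path. Inverse of :func:`load_dataset`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    loci_cfg = []
    for locus, db in dataset.dbs.items():
        fasta = out / f"{locus}.fasta"
        with open(fasta, "w") as fh:
            for name in db.alleles:
                fh.write(f">{locus}*{name}\n{db.alleles[name].nt_seq}\n")
        loci_cfg.append(
            {
                "name": locus,
                "fasta": fasta.name,
                "frame_offset": 0,
                "abs_positions": list(db.mask.positions) if db.mask else None,
            }
        )

    rows = [{"individual": i, "sex": s} for i, s in sorted(dataset.sexes.items())]
    write_tsv(pd.DataFrame(rows), out / "individuals.tsv")

    rows = []
    for (ind, locus), g in sorted(dataset.mhc_genotypes.items()):
        rows.append(
            {"individual": ind, "locus": locus,
             "allele1": "" if g.missing else g.allele1,
             "allele2": "" if g.missing else g.allele2}
        )
    write_tsv(pd.DataFrame(rows), out / "mhc_genotypes.tsv")

    rows = []
    for ind in sorted(dataset.microsat_genotypes):
        g = dataset.microsat_genotypes[ind]
        for locus in sorted(g.calls):
            call = g.calls[locus]
            rows.append(
                {"individual": ind, "locus": locus,
                 "a1": "" if call is None else call[0],
                 "a2": "" if call is None else call[1]}
            )
    write_tsv(pd.DataFrame(rows), out / "microsat_genotypes.tsv")

    rows = []
    for site in dataset.sites:
        for m, status in site.males:
            rows.append(
                {"site": site.site_id, "year": site.year,
                 "female": site.female, "male": m, "status": status}
            )
    write_tsv(pd.DataFrame(rows), out / "sites.tsv")

    rows = [{"mother": mo, "father": fa} for mo, fa in dataset.parent_pairs]
    write_tsv(pd.DataFrame(rows), out / "parent_pairs.tsv")

    cfg = {
        "loci": loci_cfg,
        "files": {
            "individuals": "individuals.tsv",
            "mhc_genotypes": "mhc_genotypes.tsv",
            "microsat_genotypes": "microsat_genotypes.tsv",
            "sites": "sites.tsv",
            "parent_pairs": "parent_pairs.tsv",
        },
    }
    if extra_config:
        cfg.update(extra_config)
    config_path = out / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return config_path
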
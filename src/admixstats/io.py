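"""Readers/writers for the text formats the pipeline touches.

VCF support is a deliberately minimal internal reader/writer for the
bi-allelic GT-only subset this pipeline produces and consumes (placeholder
REF=A/ALT=G alleles, diploid "a/b" or "a|b" genotypes, haploid male-X "a",
"./." missing). Positions are carried as 1-based VCF coordinates end to end
(one convention, no conversion step to get wrong).
Annotation and ancestry sidecars are keyed by site id and joined strictly:
a silent mismatch is the most dangerous failure mode here, so misalignment
raises.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import GenotypeMatrix, LocalAncestryCodes, AncestralPanel, X_CHROM

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_local_ancestry",
    "write_local_ancestry",
    "read_annotations",
    "write_annotations",
    "read_global_ancestry",
    "write_truth",
    "RunConfig",
]

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)
_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
_GT_HAP = {0: "0", 2: "1", -1: "."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write dosages as a minimal VCF 4.2 with placeholder REF/ALT alleles."""
    ids = list(gm.individuals.index)
    hemi = gm.hemizygous
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ids) + "\n")
        dosages = gm.dosages
        for s in range(gm.n_sites):
            row = gm.sites.iloc[s]
            gts = [
                _GT_HAP[int(dosages[i, s])] if hemi[i, s] else _GT[int(dosages[i, s])]
                for i in range(gm.n_individuals)
            ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos_bp'])}\tsite{int(row['site_id'])}\t"
                "A\tG\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def _parse_gt(token: str, line_no: int) -> tuple[int, bool]:
    """GT string -> (dosage, hemizygous); phased '|' treated like '/'."""
    gt = token.split(":", 1)[0].replace("|", "/")
    alleles = gt.split("/")
    if len(alleles) == 1:  # haploid (male X)
        a = alleles[0]
        if a == ".":
            return -1, True
        if a not in ("0", "1"):
            raise ValueError(f"line {line_no}: unsupported haploid allele {a!r}")
        return (0 if a == "0" else 2), True
    if len(alleles) != 2:
        raise ValueError(f"line {line_no}: malformed GT {token!r}")
    if "." in alleles:
        return -1, False
    try:
        dos = sum(int(a) for a in alleles)
    except ValueError as exc:
        raise ValueError(f"line {line_no}: malformed GT {token!r}") from exc
    if dos > 2 or any(a not in ("0", "1") for a in alleles):
        raise ValueError(f"line {line_no}: multi-allelic GT {token!r} unsupported")
    return dos, False


def read_vcf(path, individuals: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a bi-allelic GT-only VCF into a GenotypeMatrix.

    Multi-allelic records are skipped with a counted warning (reported via the
    returned matrix's ``sites.attrs['n_skipped']``). ``individuals`` may carry
    population/sex labels to attach; haploid GTs mark male-X entries.
    """
    ids = None
    chroms, poss, site_ids, rows = [], [], [], []
    hemi_rows = []
    n_skipped = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                parts = line.split("\t")
                if len(parts) < 10 or parts[8:9] != ["FORMAT"]:
                    raise ValueError(f"line {line_no}: malformed VCF header")
                ids = parts[9:]
                continue
            if ids is None:
                raise ValueError(f"line {line_no}: record before #CHROM header")
            parts = line.split("\t")
            if len(parts) != 9 + len(ids):
                raise ValueError(f"line {line_no}: wrong number of columns")
            if "," in parts[4]:
                n_skipped += 1
                continue
            if not parts[8].startswith("GT"):
                raise ValueError(f"line {line_no}: FORMAT must start with GT")
            parsed = [_parse_gt(tok, line_no) for tok in parts[9:]]
            rows.append([d for d, _ in parsed])
            hemi_rows.append([h for _, h in parsed])
            chroms.append(parts[0])
            try:
                poss.append(int(parts[1]))
            except ValueError as exc:
                raise ValueError(f"line {line_no}: bad POS {parts[1]!r}") from exc
            sid = parts[2]
            site_ids.append(int(sid[4:]) if sid.startswith("site") else len(site_ids))
    if ids is None:
        raise ValueError("no #CHROM header found")

    dosages = np.asarray(rows, dtype=np.int8).T if rows else np.empty((len(ids), 0), np.int8)
    hemi = np.asarray(hemi_rows, dtype=bool).T if hemi_rows else np.empty((len(ids), 0), bool)
    sites = pd.DataFrame({"site_id": site_ids, "chrom": chroms, "pos_bp": poss})

    if individuals is None:
        # infer sex from haploid X calls; default female
        is_x = sites["chrom"].to_numpy() == X_CHROM
        male = hemi[:, is_x].any(axis=1) if is_x.any() else np.zeros(len(ids), bool)
        individuals = pd.DataFrame(
            {"population": "NA", "sex": np.where(male, "male", "female")},
            index=pd.Index(ids, name="individual"),
        )
    else:
        if list(individuals.index) != ids:
            raise ValueError("individual table does not match VCF sample order")
    gm = GenotypeMatrix(dosages, individuals, sites)
    gm.sites.attrs["n_skipped"] = n_skipped
    return gm


def write_local_ancestry(lac: LocalAncestryCodes, path) -> None:
    df = pd.DataFrame(
        lac.codes.T, index=pd.Index(lac.site_ids, name="site_id"),
        columns=lac.individual_ids,
    )
    df.to_csv(path, sep="\t")


def read_local_ancestry(path, gm: GenotypeMatrix | None = None) -> LocalAncestryCodes:
    """Read a site x individual integer-code TSV; validates codes and alignment."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    codes = df.to_numpy().T
    if not np.isin(codes, np.arange(7)).all():
        bad = np.unique(codes[~np.isin(codes, np.arange(7))])
        raise ValueError(f"out-of-range diplotype codes: {bad.tolist()}")
    lac = LocalAncestryCodes(codes.astype(np.int8), df.index.to_numpy(),
                             df.columns.to_numpy())
    if gm is not None:
        lac.aligned_to(gm)
    return lac


def write_annotations(panel: AncestralPanel, path) -> None:
    panel.table.to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("coding", "ancestral_confident", "known"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_truth(cohort, path) -> None:
    """Per-individual truth table: global ancestry (auto and X), sex, population."""
    t = cohort.true_global_auto.add_suffix("_auto").join(
        cohort.true_global_x.add_suffix("_x")
    )
    t["sex"] = cohort.sex
    t["population"] = cohort.populations
    t.to_csv(path, sep="\t")


def read_global_ancestry(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


@dataclass
class RunConfig:
    """Pipeline configuration; round-trips losslessly through YAML."""

    out_dir: str = "admixstats_out"
    seed: int = 0
    n_sites: int = 20_000
    demographic: dict = field(default_factory=dict)   # DemographicSpec overrides
    missingness_max: float = 0.05
    percentile: float = 99.9
    robust_mode: str = "phylop-only"
    # minimum local-ancestry posterior for "unambiguous" backgrounds when a
    # probabilistic caller feeds the pipeline; hard 0-6 codes ignore it
    posterior_min: float = 0.90
    alpha: float = 0.05
    bonferroni_m: int | None = None
    projection_factor: float = 2.0
    stages: tuple[str, ...] = (
        "simulate", "catalog", "project", "share", "burden", "sexbias"
    )
    subgroup: str | None = None       # optional population filter (sensitivity runs)

    def __post_init__(self) -> None:
        if not (0 <= self.missingness_max <= 1):
            raise ValueError("missingness_max must lie in [0, 1]")
        if not (50 < self.percentile < 100):
            raise ValueError("percentile must lie in (50, 100)")
        if not (0 < self.posterior_min <= 1):
            raise ValueError("posterior_min must lie in (0, 1]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def digest(self) -> str:
        """Hash of the statistical configuration (output location excluded)."""
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d.pop("out_dir")
        return hashlib.sha256(
            yaml.safe_dump(d, sort_keys=True).encode()
        ).hexdigest()[:12]
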
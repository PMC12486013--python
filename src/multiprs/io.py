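"""Plain-text readers/writers for cohort artifacts.

Genotypes travel as samples x variants TSV or as minimal VCF with a DS
(dosage) FORMAT field; phenotypes and kinship as TSV.  All writers accept
``.gz`` paths (compression inferred by pandas / handled explicitly for VCF).
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd

from .cohorts import CohortPhenotypes, GenotypeMatrix, KinshipTable

__all__ = [
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_vcf_dosage",
    "read_vcf_dosage",
    "write_phenotypes_tsv",
    "read_phenotypes_tsv",
    "write_kinship_tsv",
    "read_kinship_tsv",
]


def write_genotypes_tsv(G: GenotypeMatrix, path) -> None:
    """Samples x variants dosage TSV; first columns are sample_id and ancestry."""
    frame = pd.DataFrame(G.dosages, columns=G.variants["id"])
    frame.insert(0, "ancestry", G.sample_ancestry)
    frame.insert(0, "sample_id", G.sample_ids)
    frame.to_csv(path, sep="\t", index=False, float_format="%.4g")
    vpath = _sidecar_variants_path(path)
    G.variants.to_csv(vpath, sep="\t", index=False)


def _sidecar_variants_path(path) -> Path:
    p = Path(path)
    name = p.name
    for ext in (".tsv.gz", ".tsv"):
        if name.endswith(ext):
            return p.with_name(name[: -len(ext)] + ".variants" + ext)
    return p.with_name(name + ".variants.tsv")


def read_genotypes_tsv(path) -> GenotypeMatrix:
    frame = pd.read_csv(path, sep="\t")
    variants = pd.read_csv(_sidecar_variants_path(path), sep="\t", dtype={"chrom": str})
    dosages = frame.drop(columns=["sample_id", "ancestry"]).to_numpy(float)
    return GenotypeMatrix(
        dosages, variants, frame["sample_id"].to_numpy(object), frame["ancestry"].to_numpy(object)
    )


def write_vcf_dosage(G: GenotypeMatrix, path) -> None:
    """Minimal VCF 4.2 with per-sample DS (effect-allele dosage) genotypes.

    The effect allele is written as ALT so DS counts it directly.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Effect allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(s) for s in G.sample_ids) + "\n")
        v = G.variants
        for j in range(G.n_variants):
            ds = G.dosages[:, j]
            vals = "\t".join("." if np.isnan(d) else f"{d:g}" for d in ds)
            fh.write(
                f"{v.chrom.iloc[j]}\t{v.pos.iloc[j]}\t{v.id.iloc[j]}\t"
                f"{v.other_allele.iloc[j]}\t{v.effect_allele.iloc[j]}\t.\t.\t.\tDS\t{vals}\n"
            )


def read_vcf_dosage(path, ancestry_label: str = "NA") -> GenotypeMatrix:
    """Read a DS-format VCF written by :func:`write_vcf_dosage` (or equivalent)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    rows, chroms, poss, ids, refs, alts = [], [], [], [], [], []
    with opener(path, "rt") as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.rstrip("\n").split("\t")[9:]
                continue
            f = line.rstrip("\n").split("\t")
            chroms.append(f[0]); poss.append(int(f[1])); ids.append(f[2])
            refs.append(f[3]); alts.append(f[4])
            fmt = f[8].split(":")
            ds_idx = fmt.index("DS")
            rows.append([np.nan if x.split(":")[ds_idx] == "." else float(x.split(":")[ds_idx]) for x in f[9:]])
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": np.array(poss, dtype=np.int64), "id": ids,
         "effect_allele": alts, "other_allele": refs}
    )
    dosages = np.array(rows, float).T if rows else np.zeros((len(samples), 0))
    anc = np.array([ancestry_label] * len(samples), dtype=object)
    return GenotypeMatrix(dosages, variants, np.array(samples, dtype=object), anc)


def write_phenotypes_tsv(phen: CohortPhenotypes, path) -> None:
    phen.table.to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path) -> CohortPhenotypes:
    return CohortPhenotypes(pd.read_csv(path, sep="\t"))


def write_kinship_tsv(kin: KinshipTable, path) -> None:
    out = kin.pairs.rename(columns={"sample_i": "ID1", "sample_j": "ID2", "kinship": "KIN"})
    out.to_csv(path, sep="\t", index=False)


def read_kinship_tsv(path) -> KinshipTable:
    raw = pd.read_csv(path, sep="\t")
    return KinshipTable(raw.rename(columns={"ID1": "sample_i", "ID2": "sample_j", "KIN": "kinship"}))
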
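"""Serialization: VCF 4.2, PED, marker/truth JSON, TSV/CSV tables.

Phased panels are written as VCF 4.2 with ``|``-separated GT and an AF
INFO field; unphased panels use ``/``.  Reading goes through cyvcf2.
Pedigrees use 6-column PED (FID IID PAT MAT SEX PHENO; phenotype 2 =
target-variant carrier, 1 = non-carrier, 0 = unknown).  Microsatellite
and telomere-length tables are plain TSV/CSV via pandas.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .haplotype_core import MarkerSet, SharedBlock
from .panel import MISSING, GenotypePanel, PhasedPanel, VariantSite
from .segregation import FamilyGenotypes, Individual, Pedigree
from .synthetic_data import TruthSet
from .telomere_percentiles import TLRecord

# ---------------------------------------------------------------------------
# VCF


def write_vcf(panel: PhasedPanel | GenotypePanel, path: str | Path) -> None:
    """Write a panel as uncompressed VCF 4.2 (phased GT for PhasedPanel)."""
    path = Path(path)
    phased = isinstance(panel, PhasedPanel)
    contig = panel.sites[0].chrom if panel.sites else "chr1"
    max_pos = max((s.pos for s in panel.sites), default=1)
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig},length={max_pos + 1}>",
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Global allele frequency">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.samples),
    ]
    for j, site in enumerate(panel.sites):
        info = "." if math.isnan(site.global_af) else f"AF={site.global_af:.6g}"
        gts = []
        for i in range(panel.n_samples):
            if phased:
                a, b = panel.haplotypes[2 * i, j], panel.haplotypes[2 * i + 1, j]
                sep = "|" if panel.is_phased(i, j) else "/"
                gts.append(f"{_al(a)}{sep}{_al(b)}")
            else:
                g = panel.genotypes[i, j]
                gts.append({0: "0/0", 1: "0/1", 2: "1/1"}.get(int(g), "./."))
        lines.append(
            f"{site.chrom}\t{site.pos}\t{site.id or '.'}\t{site.ref}\t{site.alt}"
            f"\t.\t.\t{info}\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")


def _al(a: int) -> str:
    return "." if a == MISSING else str(int(a))


def read_vcf(path: str | Path, phased: bool | None = None):
    """Read a VCF into a :class:`PhasedPanel` or :class:`GenotypePanel`.

    ``phased=None`` auto-detects: phased when every called genotype uses
    the ``|`` separator.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    sites: list[VariantSite] = []
    rows = []
    phased_rows = []
    for v in vcf:
        af = v.INFO.get("AF")
        sites.append(
            VariantSite(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=v.ALT[0],
                global_af=float(af) if af is not None else math.nan,
                id=v.ID,
            )
        )
        gts = v.genotypes  # [a0, a1, phased] per sample
        rows.append([(g[0], g[1]) for g in gts])
        phased_rows.append([bool(g[2]) for g in gts])
    vcf.close()

    n_sites, n_samples = len(sites), len(samples)
    all_phased = all(
        phased_rows[j][i] or rows[j][i][0] < 0
        for j in range(n_sites)
        for i in range(n_samples)
    )
    if phased is None:
        phased = all_phased

    if phased:
        haps = np.full((2 * n_samples, n_sites), MISSING, dtype=np.int8)
        pmask = np.ones((n_samples, n_sites), dtype=bool)
        for j in range(n_sites):
            for i in range(n_samples):
                a, b = rows[j][i]
                haps[2 * i, j] = a if a >= 0 else MISSING
                haps[2 * i + 1, j] = b if b >= 0 else MISSING
                pmask[i, j] = phased_rows[j][i]
        return PhasedPanel(sites=sites, samples=samples, haplotypes=haps, phased=pmask)
    geno = np.full((n_samples, n_sites), MISSING, dtype=np.int8)
    for j in range(n_sites):
        for i in range(n_samples):
            a, b = rows[j][i]
            geno[i, j] = MISSING if (a < 0 or b < 0) else a + b
    return GenotypePanel(sites=sites, samples=samples, genotypes=geno)


# ---------------------------------------------------------------------------
# PED


def write_ped(pedigrees: list[Pedigree], path: str | Path) -> None:
    """Write pedigrees as 6-column PED (FID IID PAT MAT SEX PHENO)."""
    rows = []
    for ped in pedigrees:
        for ind in ped.individuals.values():
            pheno = 0 if ind.carrier_status is None else (2 if ind.carrier_status >= 1 else 1)
            rows.append((ped.fid, ind.iid, ind.father, ind.mother, ind.sex, pheno))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_ped(path: str | Path) -> list[Pedigree]:
    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype=str)
    pedigrees = []
    for fid, group in df.groupby("fid", sort=False):
        individuals = {}
        for _, r in group.iterrows():
            pheno = int(r["pheno"])
            status = None if pheno == 0 else (1 if pheno == 2 else 0)
            individuals[r["iid"]] = Individual(
                iid=r["iid"], father=r["pat"], mother=r["mat"],
                sex=int(r["sex"]), carrier_status=status,
            )
        pedigrees.append(Pedigree(fid=str(fid), individuals=individuals))
    return pedigrees


# ---------------------------------------------------------------------------
# JSON: markers, block, truth


def _site_dict(s: VariantSite) -> dict:
    return {"chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt,
            "global_af": None if math.isnan(s.global_af) else s.global_af, "id": s.id}


def _site_from_dict(d: dict) -> VariantSite:
    return VariantSite(chrom=d["chrom"], pos=d["pos"], ref=d["ref"], alt=d["alt"],
                       global_af=d["global_af"] if d["global_af"] is not None else math.nan,
                       id=d.get("id"))


def write_markers_json(markers: MarkerSet, block: SharedBlock, path: str | Path) -> None:
    payload = {
        "block": {"chrom": block.chrom, "start": block.start, "end": block.end,
                  "span_bp": block.span, "n_carriers": block.n_carriers},
        "target": _site_dict(markers.target),
        "target_index": markers.target_index,
        "markers": [_site_dict(m) for m in markers.markers],
        "marker_indices": markers.marker_indices,
        "left_flank": _site_dict(markers.left_flank) if markers.left_flank else None,
        "right_flank": _site_dict(markers.right_flank) if markers.right_flank else None,
        "maf_threshold": markers.threshold,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_markers_json(path: str | Path) -> MarkerSet:
    d = json.loads(Path(path).read_text())
    return MarkerSet(
        markers=[_site_from_dict(m) for m in d["markers"]],
        marker_indices=list(d["marker_indices"]),
        target=_site_from_dict(d["target"]),
        target_index=d["target_index"],
        left_flank=_site_from_dict(d["left_flank"]) if d["left_flank"] else None,
        right_flank=_site_from_dict(d["right_flank"]) if d["right_flank"] else None,
        threshold=d["maf_threshold"],
    )


def write_truth_json(truth: TruthSet, path: str | Path) -> None:
    payload = {
        "founder_haplotype": truth.founder_haplotype.tolist(),
        "target_pos": truth.target_pos,
        "target_index": truth.target_index,
        "marker_indices": truth.marker_indices,
        "carriers": [list(c) for c in truth.carriers],
        "descent_intervals": [list(iv) for iv in truth.descent_intervals],
        "generations": truth.generations,
        "region_length": truth.region_length,
    }
    Path(path).write_text(json.dumps(payload) + "\n")


# ---------------------------------------------------------------------------
# tables


def write_microsat_tsv(families: list[FamilyGenotypes], fids: list[str], path: str | Path) -> None:
    rows = []
    for fid, fam in zip(fids, families):
        for iid, loci in fam.microsatellites.items():
            for locus, (a, b) in loci.items():
                rows.append((fid, iid, locus, a, b))
    pd.DataFrame(rows, columns=["fid", "iid", "locus", "allele1", "allele2"]).to_csv(
        path, sep="\t", index=False
    )


def tl_records_to_df(records: list[TLRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.sample for r in records],
            "age": [r.age for r in records],
            "measure": [r.measure for r in records],
            "rare_variant_carrier": [int(r.rare_variant_carrier) for r in records],
        }
    )


def tl_records_from_csv(path: str | Path) -> list[TLRecord]:
    df = pd.read_csv(path)
    carrier = df["rare_variant_carrier"] if "rare_variant_carrier" in df else 0
    df = df.assign(rare_variant_carrier=carrier)
    return [
        TLRecord(sample=str(r.id), age=float(r.age), measure=float(r.measure),
                 rare_variant_carrier=bool(r.rare_variant_carrier))
        for r in df.itertuples()
    ]


def write_lane_csv(intensities: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(
        {"repeat_index": np.arange(1, len(intensities) + 1), "intensity": intensities}
    ).to_csv(path, index=False)


def read_lane_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path).sort_values("repeat_index")
    return df["intensity"].to_numpy(dtype=float)
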
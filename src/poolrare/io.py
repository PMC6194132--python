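"""Plain-text interchange formats: BED panels, TSV manifests/counts/tables.

All genomic coordinates are 0-based half-open in BED and 1-based in
TSV/VCF emissions.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .models import (
    CohortGenotypes,
    Inheritance,
    Panel,
    PanelRegion,
    PoolManifest,
    SiteReadCounts,
    VariantKey,
)

__all__ = [
    "write_panel_bed",
    "read_panel_bed",
    "write_pool_manifests",
    "read_pool_manifests",
    "write_read_counts",
    "read_read_counts",
    "write_cohort_tsv",
    "read_cohort_tsv",
]


def write_panel_bed(panel: Panel, bed_path: str | Path, genes_path: str | Path) -> None:
    """Emit a panel as BED (amplicons) plus a gene-metadata TSV (inheritance)."""
    bed_path, genes_path = Path(bed_path), Path(genes_path)
    with bed_path.open("w") as fh:
        for i, r in enumerate(panel.regions):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}|amp{i + 1}\t0\t+\n")
    meta = {}
    for r in panel.regions:
        meta[r.gene_id] = r.inheritance.value
    with genes_path.open("w") as fh:
        fh.write("gene\tinheritance\n")
        for gene, inh in meta.items():
            fh.write(f"{gene}\t{inh}\n")


def read_panel_bed(bed_path: str | Path, genes_path: str | Path) -> Panel:
    meta = pd.read_csv(genes_path, sep="\t").set_index("gene")["inheritance"].to_dict()
    regions = []
    with Path(bed_path).open() as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, *_ = line.rstrip("\n").split("\t")
            gene = name.split("|")[0]
            regions.append(
                PanelRegion(gene, chrom, int(start), int(end), Inheritance(meta[gene]))
            )
    return Panel(regions=regions)


def write_pool_manifests(manifests: list[PoolManifest], path: str | Path) -> None:
    rows = [
        {"pool_id": m.pool_id, "sample_id": s, "is_control": int(s in set(m.controls))}
        for m in manifests
        for s in m.members
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pool_manifests(path: str | Path) -> list[PoolManifest]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for pool_id, grp in df.groupby("pool_id", sort=True):
        members = list(grp["sample_id"])
        controls = list(grp.loc[grp["is_control"] == 1, "sample_id"])
        out.append(PoolManifest(pool_id=str(pool_id), members=members, controls=controls))
    return out


def write_read_counts(counts: list[SiteReadCounts], path: str | Path) -> None:
    rows = [
        {
            "pool_id": c.pool_id,
            "chrom": c.chrom,
            "pos": c.pos,
            "ref": c.ref,
            "alt": c.alt,
            "depth": c.depth,
            "alt_reads": c.alt_reads,
        }
        for c in counts
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_read_counts(path: str | Path) -> list[SiteReadCounts]:
    df = pd.read_csv(path, sep="\t")
    return [
        SiteReadCounts(
            pool_id=str(r.pool_id),
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref=str(r.ref),
            alt=str(r.alt),
            depth=int(r.depth),
            alt_reads=int(r.alt_reads),
        )
        for r in df.itertuples()
    ]


def write_cohort_tsv(cohort: CohortGenotypes, path: str | Path) -> None:
    """Long-format genotypes: sample, chrom, pos, ref, alt, allele_count."""
    rows = []
    for key in cohort.variants:
        for sample, count in sorted(cohort.genotypes[key].items()):
            rows.append(
                {
                    "sample": sample,
                    "chrom": key.chrom,
                    "pos": key.pos,
                    "ref": key.ref,
                    "alt": key.alt,
                    "allele_count": count,
                }
            )
    pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref", "alt", "allele_count"]).to_csv(
        path, sep="\t", index=False
    )


def read_cohort_tsv(path: str | Path, samples: list[str] | None = None) -> CohortGenotypes:
    df = pd.read_csv(path, sep="\t")
    genotypes: dict[VariantKey, dict[str, int]] = {}
    for r in df.itertuples():
        key = VariantKey(str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        genotypes.setdefault(key, {})[str(r.sample)] = int(r.allele_count)
    all_samples = samples if samples is not None else sorted(df["sample"].unique())
    return CohortGenotypes(samples=list(all_samples), genotypes=genotypes)
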
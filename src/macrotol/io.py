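"""Readers and writers for the package's plain-text formats.

Panel tables, pupation time courses and respirometry records travel as
CSV; genotype matrices as either a simple variant-by-line TSV dialect
(columns: variant id, chrom, pos, ref, alt, then one column per line
with calls in {0, 1, .}) or minimal VCF with GT fields (inbred lines,
homozygous calls).  Wolbachia status is a two-column CSV (line,
wolbachia).  Simulation configurations round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import CausalVariant, GenotypeMatrix, SimulationConfig

__all__ = [
    "read_panel_csv",
    "write_panel_csv",
    "read_timecourse_csv",
    "write_timecourse_csv",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_genotypes_vcf",
    "write_genotypes_vcf",
    "read_wolbachia_csv",
    "write_wolbachia_csv",
    "read_genotypes",
    "load_config",
    "save_config",
]

_PANEL_COLS = ["strain", "diet", "vial", "n_seeded", "n_pupated", "n_eclosed"]


def read_panel_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_PANEL_COLS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"panel CSV missing columns: {sorted(missing)}")
    return df


def write_panel_csv(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False)


def read_timecourse_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"vial", "day", "cumulative_pupae"} - set(df.columns)
    if missing:
        raise ValueError(f"time-course CSV missing columns: {sorted(missing)}")
    return df


def write_timecourse_csv(tc: pd.DataFrame, path) -> None:
    tc.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# genotypes


def write_genotypes_tsv(g: GenotypeMatrix, path) -> None:
    calls = pd.DataFrame(g.calls, columns=g.lines).astype(object)
    calls = calls.where(g.calls >= 0, ".")
    out = pd.concat([g.variants.reset_index(drop=True), calls], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path, wolbachia: pd.Series | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["id", "chrom", "pos", "ref", "alt"]
    missing = set(meta_cols) - set(df.columns)
    if missing:
        raise ValueError(f"genotype TSV missing columns: {sorted(missing)}")
    lines = [c for c in df.columns if c not in meta_cols]
    calls = df[lines].replace(".", -1).to_numpy(dtype=float).astype(np.int8)
    if wolbachia is None:
        wolbachia = pd.Series(False, index=lines)
    return GenotypeMatrix(df[meta_cols].copy(), calls, lines, wolbachia)


def write_genotypes_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with homozygous GT calls for inbred lines."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=macrotol\n")
        chroms = dict.fromkeys(g.variants["chrom"])
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.lines) + "\n")
        gt_map = {0: "0/0", 1: "1/1", -1: "./."}
        for i, row in g.variants.iterrows():
            gts = "\t".join(gt_map[int(c)] for c in g.calls[i])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_genotypes_vcf(path, wolbachia: pd.Series | None = None) -> GenotypeMatrix:
    """Read biallelic GT calls from a VCF via cyvcf2 (het calls -> missing)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    lines = list(vcf.samples)
    meta, rows = [], []
    for idx, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            continue  # biallelic only
        meta.append(
            {
                "id": rec.ID or f"{rec.CHROM}_{rec.POS}",
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0],
            }
        )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types
        calls = np.full(len(lines), -1, dtype=np.int8)
        calls[gt == 0] = 0
        calls[gt == 3] = 1
        rows.append(calls)
    vcf.close()
    if wolbachia is None:
        wolbachia = pd.Series(False, index=lines)
    return GenotypeMatrix(
        pd.DataFrame(meta, columns=["id", "chrom", "pos", "ref", "alt"]),
        np.array(rows, dtype=np.int8).reshape(len(rows), len(lines)),
        lines,
        wolbachia,
    )


def read_genotypes(path, wolbachia: pd.Series | None = None) -> GenotypeMatrix:
    """Dispatch on extension: .vcf -> VCF reader, otherwise the TSV dialect."""
    if str(path).endswith((".vcf", ".vcf.gz")):
        return read_genotypes_vcf(path, wolbachia)
    return read_genotypes_tsv(path, wolbachia)


def write_wolbachia_csv(wolbachia: pd.Series, path) -> None:
    wolbachia.rename("wolbachia").rename_axis("line").to_frame().to_csv(path)


def read_wolbachia_csv(path) -> pd.Series:
    df = pd.read_csv(path)
    return pd.Series(df["wolbachia"].astype(bool).to_numpy(), index=df["line"], name="wolbachia")


# ---------------------------------------------------------------------------
# configuration


def save_config(config: SimulationConfig, path) -> None:
    d = asdict(config)
    d["random_effect_covariance"] = np.asarray(config.random_effect_covariance).tolist()
    d["diets"] = list(config.diets)
    d["fixed_diet_effects"] = dict(config.fixed_diet_effects)
    d["causal_variants"] = [
        {"index": cv.index, "shifts": dict(cv.shifts), "n_alt_lines": cv.n_alt_lines}
        for cv in config.causal_variants
    ]
    if callable(config.minor_line_count_distribution):
        raise ValueError("callable minor-line-count distributions cannot be serialized")
    mlc = config.minor_line_count_distribution
    d["minor_line_count_distribution"] = list(mlc) if isinstance(mlc, tuple) else mlc
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if d.get("random_effect_covariance") is not None:
        d["random_effect_covariance"] = np.asarray(d["random_effect_covariance"], dtype=float)
    mlc = d.get("minor_line_count_distribution")
    if isinstance(mlc, list):
        d["minor_line_count_distribution"] = tuple(mlc)
    d["causal_variants"] = tuple(
        CausalVariant(cv["index"], cv["shifts"], cv.get("n_alt_lines"))
        for cv in d.get("causal_variants", [])
    )
    d["eclosion_beta"] = tuple(d.get("eclosion_beta", (27.0, 3.0)))
    return SimulationConfig(**d)
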
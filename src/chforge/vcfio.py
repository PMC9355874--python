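"""Minimal VCF v4.2 round-trip for tumor-only variant-call tables.

The on-disk dialect mirrors a tumor-only caller's output: site-level FILTER
carries ``PASS``/``germline`` when all carriers agree, and the per-sample
``FT`` genotype field carries the caller filter for each observation.  Read
counts live in the standard ``DP``/``AD`` FORMAT fields and strand-specific
alt counts in the ``SAC`` pair documented in the header.  Reading uses pysam.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .resources import variant_key

__all__ = ["write_vcf", "read_vcf"]

_HEADER = """\
##fileformat=VCFv4.2
##FILTER=<ID=germline,Description="Flagged as likely germline by the somatic caller">
##FILTER=<ID=other,Description="Failed other caller-internal filters">
##INFO=<ID=GENE,Number=1,Type=String,Description="Driver panel gene symbol">
##INFO=<ID=VARCLASS,Number=1,Type=String,Description="Variant class (SNV/indel/substitution)">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Coding consequence">
##INFO=<ID=POPMAF,Number=1,Type=Float,Description="Maximum population allele frequency across reference panels">
##INFO=<ID=COSMIC,Number=1,Type=Integer,Description="Hematological somatic report count in COSMIC">
##INFO=<ID=KNOWN,Number=0,Type=Flag,Description="Present in COSMIC or dbSNP">
##INFO=<ID=ORIGIN,Number=1,Type=String,Description="Simulation truth origin (driver/germline_het/artifact); absent for real data">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##FORMAT=<ID=SAC,Number=2,Type=Integer,Description="Strand-specific alt read counts (forward,reverse)">
##FORMAT=<ID=CN,Number=1,Type=Integer,Description="Local copy number (1 or 2)">
##FORMAT=<ID=FT,Number=1,Type=String,Description="Per-sample caller filter (PASS/germline/other)">
"""


def write_vcf(calls: pd.DataFrame, path: str | Path) -> None:
    """Write a variant-call table as an uncompressed multi-sample VCF."""
    path = Path(path)
    samples = sorted(calls["sample_id"].unique())
    sample_pos = {s: i for i, s in enumerate(samples)}
    has_origin = "origin" in calls.columns

    sites: dict[str, dict] = {}
    for rec in calls.itertuples():
        key = variant_key(rec.chrom, rec.pos, rec.ref, rec.alt)
        site = sites.setdefault(key, {
            "chrom": str(rec.chrom), "pos": int(rec.pos), "ref": rec.ref,
            "alt": rec.alt, "gene": rec.gene, "var_class": rec.var_class,
            "consequence": rec.consequence, "pop_maf": float(rec.pop_maf),
            "cosmic": int(rec.cosmic_heme_count), "known": bool(rec.is_known),
            "origin": getattr(rec, "origin", None) if has_origin else None,
            "calls": {},
        })
        site["calls"][rec.sample_id] = (
            int(rec.depth), int(rec.alt_depth), int(rec.alt_fwd),
            int(rec.alt_rev), int(rec.copy_number), str(rec.caller_filter))

    def _chrom_sort(c: str):
        return (0, int(c)) if c.isdigit() else (1, c)

    lines = [_HEADER.rstrip("\n")]
    for chrom in sorted({s["chrom"] for s in sites.values()}, key=_chrom_sort):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))

    for key in sorted(sites, key=lambda k: (_chrom_sort(sites[k]["chrom"]),
                                            sites[k]["pos"], sites[k]["ref"],
                                            sites[k]["alt"])):
        s = sites[key]
        filters = {f for *_, f in s["calls"].values()}
        site_filter = filters.pop() if len(filters) == 1 else "."
        info = (f"GENE={s['gene']};VARCLASS={s['var_class']};"
                f"CSQ={s['consequence']};POPMAF={s['pop_maf']:.6g};"
                f"COSMIC={s['cosmic']}")
        if s["known"]:
            info += ";KNOWN"
        if s["origin"]:
            info += f";ORIGIN={s['origin']}"
        fmt_cells = []
        for sample in samples:
            if sample in s["calls"]:
                dp, ad, fwd, rev, cn, ft = s["calls"][sample]
                fmt_cells.append(f"0/1:{dp}:{dp - ad},{ad}:{fwd},{rev}:{cn}:{ft}")
            else:
                fmt_cells.append("./.:.:.:.:.:.")
        lines.append("\t".join([
            s["chrom"], str(s["pos"]), ".", s["ref"], s["alt"], ".",
            site_filter, info, "GT:DP:AD:SAC:CN:FT", *fmt_cells]))
    path.write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read a tumor-only dialect VCF back into the variant-call table."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = rec.info
            site_filter = rec.filter.keys()[0] if len(rec.filter.keys()) else "."
            for sample, call in rec.samples.items():
                gt = call.get("GT")
                if gt is None or all(a is None for a in gt):
                    continue
                dp = int(call["DP"])
                ad = call["AD"]
                fwd, rev = call["SAC"]
                flt = call.get("FT") or site_filter
                rows.append({
                    "sample_id": sample,
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "gene": info.get("GENE"),
                    "var_class": info.get("VARCLASS"),
                    "consequence": info.get("CSQ"),
                    "depth": dp,
                    "alt_depth": int(ad[1]),
                    "alt_fwd": int(fwd),
                    "alt_rev": int(rev),
                    "vaf": int(ad[1]) / dp if dp else float("nan"),
                    "caller_filter": flt,
                    "pop_maf": float(info.get("POPMAF", 0.0)),
                    "cosmic_heme_count": int(info.get("COSMIC", 0)),
                    "is_known": bool(info.get("KNOWN", False)),
                    "copy_number": int(call["CN"]),
                })
                if "ORIGIN" in info:
                    rows[-1]["origin"] = info["ORIGIN"]
    calls = pd.DataFrame(rows)
    if len(calls):
        calls["variant_key"] = [
            variant_key(c, p, r, a)
            for c, p, r, a in zip(calls["chrom"], calls["pos"],
                                  calls["ref"], calls["alt"])
        ]
    return calls
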
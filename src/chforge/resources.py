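"""Driver-variant resources: hotspot lists, whitelist rules and COSMIC counts.

A :class:`DriverResource` bundles the three external evidence tables used by
the filtering chain:

* ``hotspots`` — variant keys (``chrom:pos:ref:alt``) of recurrent driver
  changes that are accepted irrespective of other evidence;
* ``whitelist_rules`` — per-gene rules accepting particular consequence
  classes over a position interval (typically truncating variants across the
  gene body of loss-of-function drivers);
* ``cosmic_counts`` — number of times a variant has been reported as somatic
  in hematological cancers.

The module also builds a deterministic **synthetic panel** of ten common CH
driver genes with hotspot/recurrent/whitelist site pools.  The panel layout is
fixed (independent of any simulation seed) so that resource files, simulated
cohorts and tests all refer to the same reference data, mirroring how a real
analysis pins externally curated tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DriverResource",
    "PanelSite",
    "PanelLayout",
    "default_panel_layout",
    "default_resources",
    "variant_key",
]

#: The ten most common CH driver genes (descending carrier frequency).
PANEL_GENES: tuple[str, ...] = (
    "DNMT3A", "TET2", "ASXL1", "PPM1D", "TP53",
    "JAK2", "SRSF2", "SF3B1", "GNB1", "ATM",
)

#: Carrier-frequency weights proportional to the panel's rank ordering.
DEFAULT_GENE_FREQUENCIES: dict[str, float] = {
    g: (len(PANEL_GENES) - i) / sum(range(1, len(PANEL_GENES) + 1))
    for i, g in enumerate(PANEL_GENES)
}

_GENE_CHROM = {
    "DNMT3A": "2", "TET2": "4", "ASXL1": "20", "PPM1D": "17", "TP53": "17",
    "JAK2": "9", "SRSF2": "17", "SF3B1": "2", "GNB1": "1", "ATM": "11",
}

_LOF_CONSEQUENCES = frozenset({"frameshift", "nonsense", "splice_site"})

# Fixed entropy for the panel layout; NOT a simulation seed.  Changing it
# changes the synthetic reference tables, like swapping a COSMIC release.
_PANEL_ENTROPY = 760_244_311


def variant_key(chrom, pos, ref, alt) -> str:
    """Normalized variant key ``chrom:pos:REF:ALT`` (1-based position)."""
    return f"{chrom}:{int(pos)}:{str(ref).upper()}:{str(alt).upper()}"


@dataclass(frozen=True)
class PanelSite:
    """One mutable site of the synthetic driver panel."""

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str
    var_class: str          # SNV | indel | substitution
    site_type: str          # hotspot | cosmic | whitelist
    cosmic_heme_count: int

    @property
    def key(self) -> str:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)


@dataclass
class DriverResource:
    """External driver-evidence tables used by the filter chain."""

    hotspots: set[str] = field(default_factory=set)
    #: (gene, allowed consequences, interval start, interval end), 1-based inclusive.
    whitelist_rules: list[tuple[str, frozenset[str], int, int]] = field(default_factory=list)
    cosmic_counts: dict[str, int] = field(default_factory=dict)

    def is_hotspot(self, key: str) -> bool:
        return key in self.hotspots

    def cosmic_count(self, key: str) -> int:
        return int(self.cosmic_counts.get(key, 0))

    def in_cosmic(self, key: str) -> bool:
        return self.cosmic_count(key) > 0

    def whitelist_match(self, gene: str, consequence: str, pos: int) -> bool:
        gene = str(gene).upper()
        for g, consequences, start, end in self.whitelist_rules:
            if g == gene and consequence in consequences and start <= pos <= end:
                return True
        return False

    # ------------------------------------------------------------------ IO
    def to_dir(self, path: str | Path) -> None:
        """Write hotspots/whitelist/cosmic TSVs into ``path``."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        hs = pd.DataFrame(
            [k.split(":") for k in sorted(self.hotspots)],
            columns=["chrom", "pos", "ref", "alt"],
        )
        hs.insert(0, "gene", "")
        hs["protein_change"] = ""
        hs.to_csv(path / "hotspots.tsv", sep="\t", index=False)
        wl = pd.DataFrame(
            [(g, ",".join(sorted(c)), s, e) for g, c, s, e in self.whitelist_rules],
            columns=["gene", "consequence_set", "start", "end"],
        )
        wl.to_csv(path / "whitelist.tsv", sep="\t", index=False)
        cm = pd.DataFrame(
            sorted(self.cosmic_counts.items()), columns=["variant_key", "heme_count"]
        )
        cm.to_csv(path / "cosmic.tsv", sep="\t", index=False)

    @classmethod
    def from_dir(cls, path: str | Path) -> "DriverResource":
        path = Path(path)
        hs = pd.read_csv(path / "hotspots.tsv", sep="\t", dtype={"chrom": str})
        hotspots = {
            variant_key(r.chrom, r.pos, r.ref, r.alt) for r in hs.itertuples()
        }
        wl = pd.read_csv(path / "whitelist.tsv", sep="\t")
        rules = [
            (str(r.gene).upper(), frozenset(str(r.consequence_set).split(",")),
             int(r.start), int(r.end))
            for r in wl.itertuples()
        ]
        cm = pd.read_csv(path / "cosmic.tsv", sep="\t")
        counts = dict(zip(cm["variant_key"], cm["heme_count"].astype(int)))
        return cls(hotspots=hotspots, whitelist_rules=rules, cosmic_counts=counts)


@dataclass
class PanelLayout:
    """Deterministic site pools of the synthetic ten-gene driver panel."""

    genes: tuple[str, ...]
    intervals: dict[str, tuple[str, int, int]]     # gene -> (chrom, start, end)
    hotspot_sites: dict[str, list[PanelSite]]
    cosmic_sites: dict[str, list[PanelSite]]       # recurrent, COSMIC-reported
    whitelist_sites: dict[str, list[PanelSite]]    # truncating, whitelist-only
    germline_sites: list[PanelSite]                # population het SNPs w/ MAF
    germline_mafs: dict[str, float]                # key -> population MAF
    artifact_sites: list[PanelSite]

    def driver_sites(self, gene: str) -> list[PanelSite]:
        return (self.hotspot_sites[gene] + self.cosmic_sites[gene]
                + self.whitelist_sites[gene])

    def resource(self) -> DriverResource:
        res = DriverResource()
        for g in self.genes:
            res.hotspots.update(s.key for s in self.hotspot_sites[g])
            for s in self.hotspot_sites[g] + self.cosmic_sites[g]:
                if s.cosmic_heme_count > 0:
                    res.cosmic_counts[s.key] = s.cosmic_heme_count
            chrom, start, end = self.intervals[g]
            res.whitelist_rules.append((g, _LOF_CONSEQUENCES, start, end))
        return res


_BASES = np.array(list("ACGT"))


def _snv(rng: np.random.Generator) -> tuple[str, str]:
    ref, alt = rng.choice(4, size=2, replace=False)
    return _BASES[ref], _BASES[alt]


def default_panel_layout() -> PanelLayout:
    """Build the fixed synthetic panel (memoized)."""
    global _LAYOUT_CACHE
    if _LAYOUT_CACHE is not None:
        return _LAYOUT_CACHE
    rng = np.random.default_rng(np.random.SeedSequence(_PANEL_ENTROPY))
    intervals: dict[str, tuple[str, int, int]] = {}
    hotspot_sites: dict[str, list[PanelSite]] = {}
    cosmic_sites: dict[str, list[PanelSite]] = {}
    whitelist_sites: dict[str, list[PanelSite]] = {}
    germline_sites: list[PanelSite] = []
    germline_mafs: dict[str, float] = {}
    artifact_sites: list[PanelSite] = []

    for i, gene in enumerate(PANEL_GENES):
        chrom = _GENE_CHROM[gene]
        start = 1_000_000 * (i + 1) + 1
        end = start + 5_999
        intervals[gene] = (chrom, start, end)
        used: set[int] = set()

        def _pos() -> int:
            while True:
                p = int(rng.integers(start, end + 1))
                if p not in used:
                    used.add(p)
                    return p

        hotspot_sites[gene] = []
        for _ in range(3):
            ref, alt = _snv(rng)
            hotspot_sites[gene].append(PanelSite(
                gene, chrom, _pos(), ref, alt, "missense", "SNV",
                "hotspot", int(20 + rng.poisson(60))))

        cosmic_sites[gene] = []
        for _ in range(12):
            cons = str(rng.choice(
                ["missense", "nonsense", "frameshift", "splice_site"],
                p=[0.5, 0.2, 0.2, 0.1]))
            if cons == "frameshift":
                ref = str(rng.choice(_BASES))
                alt = ref + str(rng.choice(_BASES))
                var_class = "indel"
            else:
                ref, alt = _snv(rng)
                var_class = "SNV"
            cosmic_sites[gene].append(PanelSite(
                gene, chrom, _pos(), ref, alt, cons, var_class,
                "cosmic", int(7 + rng.poisson(20))))

        whitelist_sites[gene] = []
        for _ in range(8):
            cons = str(rng.choice(["nonsense", "frameshift", "splice_site"],
                                  p=[0.4, 0.4, 0.2]))
            if cons == "frameshift":
                ref = str(rng.choice(_BASES))
                alt = ref + str(rng.choice(_BASES))
                var_class = "indel"
            else:
                ref, alt = _snv(rng)
                var_class = "SNV"
            whitelist_sites[gene].append(PanelSite(
                gene, chrom, _pos(), ref, alt, cons, var_class, "whitelist", 0))

        # Germline het SNPs overlapping the gene footprint; MAF spans the
        # common-to-rare range so the population-frequency screens bite.
        for _ in range(20):
            ref, alt = _snv(rng)
            site = PanelSite(gene, chrom, _pos(), ref, alt,
                             str(rng.choice(["missense", "synonymous"])),
                             "SNV", "germline", 0)
            germline_sites.append(site)
            germline_mafs[site.key] = float(10 ** rng.uniform(-5.0, -1.5))

        for _ in range(5):
            ref, alt = _snv(rng)
            artifact_sites.append(PanelSite(
                gene, chrom, _pos(), ref, alt, "missense", "SNV", "artifact", 0))

    _LAYOUT_CACHE = PanelLayout(
        genes=PANEL_GENES, intervals=intervals, hotspot_sites=hotspot_sites,
        cosmic_sites=cosmic_sites, whitelist_sites=whitelist_sites,
        germline_sites=germline_sites, germline_mafs=germline_mafs,
        artifact_sites=artifact_sites)
    return _LAYOUT_CACHE


_LAYOUT_CACHE: PanelLayout | None = None


def default_resources() -> DriverResource:
    """DriverResource for the synthetic ten-gene panel."""
    return default_panel_layout().resource()
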
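"""The eleven dopaminergic candidate variants studied: eight SNPs and three
VNTRs, with their additive codings, published minor-allele frequencies and
genotype-group counts, and the dopamine-increasing effect allele used by the
polygenic risk score.

The counted allele follows the published genotype-column order (the allele
whose copy number increases across the 0/1/2 columns). For the two variants
whose functional allele *decreases* dopamine signalling via the focal repeat
(the DRD5 148-bp and DAT1 480-bp repeats), the effect allele is the absence
of the focal repeat. The mapping is also shipped as an editable YAML config
(``data/effect_alleles.yaml``).
"""

from __future__ import annotations

from dataclasses import dataclass

from .genotype import ABSENCE, VariantSpec


@dataclass(frozen=True)
class PanelVariant:
    spec: VariantSpec
    published_maf: float
    published_n: int
    genotype_counts: tuple[int, int, int]  # in counted-allele 0/1/2 order


_DRD4_REPEATS = tuple(str(r) for r in range(2, 12))
_DRD5_REPEATS = tuple(str(r) for r in range(130, 168, 2))
_DAT1_REPEATS = ("440", "480", "520")

VARIANT_PANEL: tuple[PanelVariant, ...] = (
    PanelVariant(VariantSpec("rs265981", "snp", ("G", "A"), "A", "A", "G", "DRD1"),
                 0.37, 7873, (3069, 3771, 1033)),
    PanelVariant(VariantSpec("rs6275", "snp", ("G", "A"), "A", "A", "A", "DRD2"),
                 0.30, 7734, (3812, 3262, 660)),
    PanelVariant(VariantSpec("rs1800497", "snp", ("G", "A"), "A", "A", "A", "DRD2"),
                 0.19, 8756, (5714, 2684, 358)),
    PanelVariant(VariantSpec("rs6280", "snp", ("C", "T"), "T", "C", "T", "DRD3"),
                 0.31, 7734, (734, 3272, 3728)),
    PanelVariant(VariantSpec("rs1800955", "snp", ("T", "C"), "C", "C", "T", "DRD4"),
                 0.43, 2152, (680, 1103, 369)),
    PanelVariant(VariantSpec("DRD4_exon3_VNTR", "vntr", _DRD4_REPEATS, "7",
                             None, "7", "DRD4"),
                 0.19, 2476, (1624, 756, 96)),
    PanelVariant(VariantSpec("DRD5_upstream_VNTR", "vntr", _DRD5_REPEATS, "148",
                             None, ABSENCE, "DRD5"),
                 0.49, 2480, (607, 1302, 571)),
    PanelVariant(VariantSpec("rs1611115", "snp", ("T", "C"), "C", "T", "T", "DBH"),
                 0.21, 3140, (137, 1035, 1968)),
    PanelVariant(VariantSpec("rs2519152", "snp", ("C", "T"), "T", "C", "T", "DBH"),
                 0.46, 8139, (1752, 3948, 2439)),
    PanelVariant(VariantSpec("DAT1_3utr_VNTR", "vntr", _DAT1_REPEATS, "480",
                             None, ABSENCE, "DAT1"),
                 0.25, 2464, (162, 925, 1377)),
    PanelVariant(VariantSpec("rs4680", "snp", ("G", "A"), "A", "A", "G", "COMT"),
                 0.45, 8755, (1779, 4339, 2637)),
)

PANEL_BY_ID = {pv.spec.variant_id: pv for pv in VARIANT_PANEL}

#: The four sample-size/MAF anchors the power analysis is run at: the smallest
#: and largest fingerprint-only samples and the smallest and largest samples
#: that include imputed data.
POWER_ANCHORS = (
    {"variant_id": "rs1800955", "n_individuals": 2152, "maf": 0.43},
    {"variant_id": "rs1611115", "n_individuals": 3140, "maf": 0.21},
    {"variant_id": "rs6275", "n_individuals": 7734, "maf": 0.30},
    {"variant_id": "rs1800497", "n_individuals": 8756, "maf": 0.19},
)
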
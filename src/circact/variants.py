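"""Variant-based gene integrity: zero out genes carrying deleterious mutations.

A gene's product can only transmit signal if it is both expressed and
functional.  Variants whose consequence is deleterious per se (stop gain,
stop loss, splicing disruption), or whose pathogenicity and conservation
scores are both beyond their cutoffs, mark the gene as broken in that sample
subject to the inheritance mode; the gene's scaled expression is then
multiplied by 0 so no signal can pass through nodes that require it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

#: consequence types deleterious regardless of any score
DELETERIOUS_CONSEQUENCES = frozenset({"stop_gain", "stop_loss", "splicing_disrupting"})
#: consequence vocabulary we recognise; others trigger a warning
KNOWN_CONSEQUENCES = DELETERIOUS_CONSEQUENCES | frozenset({
    "missense", "synonymous", "inframe_indel", "frameshift",
    "utr", "intronic", "intergenic", "upstream", "downstream",
})


@dataclass(frozen=True)
class VariantCall:
    """One variant observed in one sample, annotated at the gene level.

    ``sift`` is ascending-benign in [0,1] (low = damaging), ``polyphen``
    ascending-damaging in [0,1], ``conservation`` a phastCons-like score in
    [0,1]; any of the three may be missing.
    """

    sample: str
    gene: str
    consequence: str
    zygosity: str  # "het" | "hom"
    sift: float | None = None
    polyphen: float | None = None
    conservation: float | None = None

    def __post_init__(self) -> None:
        if self.zygosity not in ("het", "hom"):
            raise ValueError(f"zygosity must be 'het' or 'hom', got {self.zygosity!r}")
        for name in ("sift", "polyphen", "conservation"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} score {v} outside [0,1]")


@dataclass(frozen=True)
class IntegrityThresholds:
    """Score cutoffs beyond which a variant counts as damaging.

    Defaults follow the scores' conventional damaging ranges; all
    configurable.  The score rule fires when (sift <= sift_max OR
    polyphen >= polyphen_min) AND conservation >= conservation_min.
    """

    sift_max: float = 0.05
    polyphen_min: float = 0.85
    conservation_min: float = 0.95


def _qualifies(call: VariantCall, t: IntegrityThresholds) -> bool:
    cons = call.consequence.lower()
    if cons not in KNOWN_CONSEQUENCES:
        logger.warning("unknown consequence %r (sample %s, gene %s): "
                       "treated as non-deleterious", call.consequence,
                       call.sample, call.gene)
        return False
    if cons in DELETERIOUS_CONSEQUENCES:
        return True
    pathogenic = (
        (call.sift is not None and call.sift <= t.sift_max)
        or (call.polyphen is not None and call.polyphen >= t.polyphen_min)
    )
    conserved = call.conservation is not None and call.conservation >= t.conservation_min
    return pathogenic and conserved


def compute_integrity(
    calls: list[VariantCall],
    thresholds: IntegrityThresholds | None = None,
    inheritance: str = "dominant",
    genes=None,
    samples=None,
) -> pd.DataFrame:
    """Binary genes x samples integrity matrix from variant calls.

    A (gene, sample) cell is 0 when the qualifying variants satisfy the
    inheritance mode — dominant: any single qualifying call; recessive: a
    homozygous qualifying call, or at least two distinct heterozygous
    qualifying calls in the gene (compound het, phase ignored) — and 1
    otherwise.  Genes and samples without calls default to 1; ``genes`` /
    ``samples`` extend the index beyond what the calls mention.
    """
    if inheritance not in ("dominant", "recessive"):
        raise ValueError(f"inheritance must be 'dominant' or 'recessive', "
                         f"got {inheritance!r}")
    t = thresholds or IntegrityThresholds()
    hits: dict[tuple[str, str], list[VariantCall]] = {}
    for c in calls:
        if _qualifies(c, t):
            hits.setdefault((c.gene, c.sample), []).append(c)

    all_genes = sorted({c.gene for c in calls} | set(genes or ()))
    all_samples = sorted({c.sample for c in calls} | set(samples or ()))
    im = pd.DataFrame(1, index=all_genes, columns=all_samples, dtype=int)
    for (gene, sample), group in hits.items():
        if inheritance == "dominant":
            broken = True
        else:
            n_hom = sum(1 for c in group if c.zygosity == "hom")
            n_het = sum(1 for c in group if c.zygosity == "het")
            broken = n_hom >= 1 or n_het >= 2
        if broken:
            im.loc[gene, sample] = 0
    return im


def apply_integrity(m: pd.DataFrame, im: pd.DataFrame) -> pd.DataFrame:
    """Multiply expression by integrity; genes/samples absent from ``im`` pass through."""
    factor = im.reindex(index=m.index, columns=m.columns, fill_value=1)
    return m * factor.astype(float)


@dataclass(frozen=True)
class VcfFieldMap:
    """Names of the INFO fields carrying gene-level annotations."""

    gene: str = "GENE"
    consequence: str = "CONSEQ"
    sift: str = "SIFT"
    polyphen: str = "POLYPHEN"
    conservation: str = "PHASTCONS"


def read_vcf_calls(path, fields: VcfFieldMap | None = None) -> list[VariantCall]:
    """Read annotated variant calls from a VCF 4.x file.

    Per-sample genotypes give zygosity (het/hom-alt); homozygous-reference
    and missing genotypes produce no call.  Annotations are read from the
    INFO fields named in ``fields``.
    """
    from cyvcf2 import VCF

    fields = fields or VcfFieldMap()
    vcf = VCF(str(path))
    samples = vcf.samples
    calls: list[VariantCall] = []
    for rec in vcf:
        gene = rec.INFO.get(fields.gene)
        if gene is None:
            logger.warning("%s: variant at %s:%d has no %s INFO field; skipped",
                           path, rec.CHROM, rec.POS, fields.gene)
            continue
        cons = rec.INFO.get(fields.consequence, "unknown")

        def _score(key):
            v = rec.INFO.get(key)
            return None if v is None else float(v)

        sift = _score(fields.sift)
        polyphen = _score(fields.polyphen)
        conservation = _score(fields.conservation)
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        for sample, gt in zip(samples, rec.gt_types):
            if gt == 1:
                zyg = "het"
            elif gt == 3:
                zyg = "hom"
            else:
                continue
            calls.append(VariantCall(sample, str(gene), str(cons), zyg,
                                     sift, polyphen, conservation))
    return calls


def read_calls_tsv(path) -> list[VariantCall]:
    """TSV alternative to VCF: columns sample, gene, consequence, zygosity,
    and optional sift, polyphen, conservation."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower() for c in df.columns]

    def _opt(row, key):
        v = row.get(key)
        return None if v is None or pd.isna(v) else float(v)

    return [
        VariantCall(str(r["sample"]), str(r["gene"]), str(r["consequence"]),
                    str(r["zygosity"]), _opt(r, "sift"), _opt(r, "polyphen"),
                    _opt(r, "conservation"))
        for r in df.to_dict("records")
    ]
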
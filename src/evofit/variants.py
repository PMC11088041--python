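"""Triage of variant calls from evolved clones.

Three operations identify candidate adaptive mutations after upstream
read mapping and variant calling (which this package does not perform):

* frequency filtering — haploid clones isolated from single colonies are
  expected to carry their true variants at frequencies tending to 100%,
  so calls below a cut-off (default 50%, inclusive) are discarded;
* parental subtraction — for a clone whose progenitor is a recombinant of
  two parental haploid genomes, de novo variants are those whose
  (chrom, pos, ref, alt) key is absent from the catalogue of parental
  polymorphisms;
* parallelism — genes mutated independently in two or more clones, the
  classic signature of adaptive selection in laboratory evolution.

Coordinates are 1-based throughout, as in VCF.  Alleles are reduced to
their minimal representation (shared suffix then prefix trimmed, with the
position advanced) before keying, so equivalent indel spellings compare
equal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import pandas as pd
import pysam

__all__ = [
    "VariantRecord",
    "VariantKey",
    "normalize_variant",
    "read_variants",
    "write_variants",
    "filter_by_frequency",
    "subtract_parental",
    "parallel_genes",
    "venn_regions",
    "TSV_COLUMNS",
]

logger = logging.getLogger(__name__)

TSV_COLUMNS = ["chrom", "pos", "ref", "alt", "frequency", "gene", "effect", "clone_id"]

INTERGENIC = "intergenic"


class VariantKey(NamedTuple):
    """Identity of a variant for coordinate comparison."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str


@dataclass(frozen=True)
class VariantRecord:
    """One called variant (single ALT allele)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    frequency: float = 1.0
    gene: str = INTERGENIC
    effect: str = ""
    clone_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (1-based coordinates), got {self.pos}")
        if not (0 <= self.frequency <= 1):
            raise ValueError(f"frequency must lie in [0, 1], got {self.frequency}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("alleles must be non-empty")

    def key(self, *, position_only: bool = False) -> tuple:
        """Comparison key; by default the full normalised allele tuple."""
        norm = normalize_variant(self)
        if position_only:
            return (norm.chrom, norm.pos)
        return VariantKey(norm.chrom, norm.pos, norm.ref_allele, norm.alt_allele)


def normalize_variant(rec: VariantRecord) -> VariantRecord:
    """Minimal representation: trim shared suffix, then shared prefix.

    Prefix trimming advances ``pos`` by the number of bases removed.  At
    least one base is kept on each allele.  SNVs are returned unchanged.
    """
    ref, alt, pos = rec.ref_allele, rec.alt_allele, rec.pos
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if (ref, alt, pos) == (rec.ref_allele, rec.alt_allele, rec.pos):
        return rec
    return replace(rec, ref_allele=ref, alt_allele=alt, pos=pos)


def _info_get(variant: pysam.VariantRecord, key: str, default):
    # pysam raises on INFO keys absent from the header, not just from the record
    try:
        return variant.info[key]
    except (KeyError, ValueError):
        return default


def _vcf_frequency(variant: pysam.VariantRecord, alt_index: int) -> float:
    """Allele fraction of the alt_index-th ALT, from INFO/AF or a sample AF."""
    af = _info_get(variant, "AF", None)
    if af is None:
        for sample in variant.samples.values():
            try:
                af = sample["AF"]
            except (KeyError, ValueError):
                continue
            if af is not None:
                break
    if af is None:
        raise ValueError(
            f"{variant.chrom}:{variant.pos}: no allele-frequency source found "
            "(expected INFO/AF or a per-sample FORMAT/AF field)"
        )
    if isinstance(af, (tuple, list)):
        return float(af[alt_index])
    return float(af)


def _read_vcf(path: Path, clone_id: str) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for variant in vcf:
            alts = variant.alts or ()
            gene = _info_get(variant, "GENE", INTERGENIC)
            if isinstance(gene, tuple):
                gene = gene[0]
            effect = _info_get(variant, "EFFECT", "")
            if isinstance(effect, tuple):
                effect = effect[0]
            for i, alt in enumerate(alts):
                records.append(
                    VariantRecord(
                        chrom=variant.chrom,
                        pos=variant.pos,
                        ref_allele=variant.ref,
                        alt_allele=alt,
                        frequency=_vcf_frequency(variant, i),
                        gene=str(gene),
                        effect=str(effect),
                        clone_id=clone_id,
                    )
                )
    return records


def _read_tsv(path: Path, clone_id: str, strict: bool) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in ("chrom", "pos", "ref", "alt") if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; expected columns {TSV_COLUMNS}"
        )
    if "frequency" not in df.columns:
        raise ValueError(
            f"{path}: no frequency source; expected a 'frequency' column with allele fractions"
        )
    records: list[VariantRecord] = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            records.append(
                VariantRecord(
                    chrom=str(row["chrom"]),
                    pos=int(row["pos"]),
                    ref_allele=str(row["ref"]),
                    alt_allele=str(row["alt"]),
                    frequency=float(row["frequency"]),
                    gene=str(row.get("gene", INTERGENIC) or INTERGENIC),
                    effect=str(row.get("effect", "") or ""),
                    clone_id=str(row.get("clone_id", clone_id) or clone_id),
                )
            )
        except (TypeError, ValueError) as err:
            if strict:
                raise ValueError(f"{path}: malformed record at line {line_no}: {err}") from err
            logger.warning("%s: skipping malformed record at line %d: %s", path, line_no, err)
    return records


def read_variants(
    path: str | Path,
    dialect: str | None = None,
    *,
    clone_id: str = "",
    strict: bool = True,
) -> list[VariantRecord]:
    """Read variant calls from a VCF or the documented TSV dialect.

    Multi-allelic VCF rows are split into one record per ALT allele.
    The dialect is inferred from the file suffix when not given.  In
    lenient mode (``strict=False``) malformed TSV rows are skipped with a
    logged warning instead of raising.
    """
    path = Path(path)
    if dialect is None:
        dialect = "vcf" if path.name.endswith((".vcf", ".vcf.gz")) else "tsv"
    if dialect == "vcf":
        return _read_vcf(path, clone_id)
    if dialect == "tsv":
        return _read_tsv(path, clone_id, strict)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'vcf' or 'tsv')")


def write_variants(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write records as the TSV dialect read back by :func:`read_variants`."""
    df = pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref_allele,
                "alt": r.alt_allele,
                "frequency": r.frequency,
                "gene": r.gene,
                "effect": r.effect,
                "clone_id": r.clone_id,
            }
            for r in records
        ],
        columns=TSV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def filter_by_frequency(
    variants: Iterable[VariantRecord], min_freq: float = 0.5
) -> list[VariantRecord]:
    """Keep variants called at or above the frequency cut-off (inclusive)."""
    return [v for v in variants if v.frequency >= min_freq]


def subtract_parental(
    child_variants: Iterable[VariantRecord],
    parental_polymorphisms: Iterable[VariantRecord],
    *,
    position_only: bool = False,
    on_unknown_contig: str = "warn",
) -> list[VariantRecord]:
    """De novo variants: child records absent from the parental catalogue.

    Matching uses the full normalised (chrom, pos, ref, alt) key by
    default; ``position_only=True`` matches on coordinates alone, which is
    how spreadsheet-era comparisons were often done but will also drop
    co-located distinct alleles.  Input order is preserved.

    Child records on contigs never seen in the parental catalogue trigger
    a warning (``on_unknown_contig="error"`` raises; ``"ignore"`` is
    silent) since they usually indicate mismatched reference genomes.
    """
    child = list(child_variants)
    parental = list(parental_polymorphisms)
    parental_keys = {p.key(position_only=position_only) for p in parental}
    if parental:
        parental_contigs = {p.chrom for p in parental}
        unknown = sorted({c.chrom for c in child} - parental_contigs)
        if unknown:
            msg = f"child contigs absent from the parental catalogue: {unknown}"
            if on_unknown_contig == "error":
                raise ValueError(msg)
            if on_unknown_contig == "warn":
                logger.warning(msg)
    return [c for c in child if c.key(position_only=position_only) not in parental_keys]


def parallel_genes(
    clone_to_variants: Mapping[str, Iterable[VariantRecord]],
    *,
    include_intergenic: bool = False,
) -> tuple[dict[str, frozenset[str]], dict[str, frozenset[str]]]:
    """Map each mutated gene to the clones carrying it; flag parallel hits.

    Returns ``(gene_to_clones, parallel)`` where ``parallel`` is the
    subset of genes mutated in two or more clones — candidate adaptive
    targets.  Records annotated as intergenic are excluded unless
    ``include_intergenic=True``.
    """
    if len(clone_to_variants) < 2:
        raise ValueError("parallelism needs variant lists from at least 2 clones")
    gene_clones: dict[str, set[str]] = {}
    for clone_id, variants in clone_to_variants.items():
        for v in variants:
            if v.gene == INTERGENIC and not include_intergenic:
                continue
            gene_clones.setdefault(v.gene, set()).add(clone_id)
    gene_to_clones = {g: frozenset(c) for g, c in gene_clones.items()}
    parallel = {g: c for g, c in gene_to_clones.items() if len(c) >= 2}
    return gene_to_clones, parallel


def venn_regions(
    gene_to_clones: Mapping[str, frozenset[str]]
) -> dict[frozenset[str], set[str]]:
    """Group genes by the exact set of clones mutating them.

    The region sizes of a Venn diagram over clones: each key is a clone
    membership pattern, each value the set of genes with exactly that
    pattern.  Region sizes sum to the number of distinct mutated genes.
    """
    regions: dict[frozenset[str], set[str]] = {}
    for gene, clones in gene_to_clones.items():
        regions.setdefault(frozenset(clones), set()).add(gene)
    return regions
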
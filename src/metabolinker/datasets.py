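"""Packaged published tables and fixture builders.

Three small tables from the obese-mouse study are shipped with the
package: the phenotype summary (body weight, body fat percentage,
serum triglycerides and NEFA per line x sex x diet cell), the table of
31 serum metabolites that differ between the obese line and the pooled
lean lines, and the table of 29 sequence variants found between the
obese and reference lines in the Ccna2 promoter and transcript.

The Ccna2 gene model used to classify those variants is synthetic in
its exon boundaries: the published record fixes the variant positions,
the 420-bp promoter window, which exon each variant falls in and the
codon readout of the two coding SNPs, but not the full exon structure;
the intervals below were constructed once to satisfy every published
constraint and are a stand-in for the real transcript annotation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .simulate import generate_sequences
from .variants import GeneModel, Variant, call_variants

CCNA2_CHROM = "3"


def _read(name: str) -> pd.DataFrame:
    with resources.files("metabolinker").joinpath("data", name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_phenotypes() -> pd.DataFrame:
    """Published phenotype cell means/SDs (trait, unit, line, sex,
    diet, mean, sd)."""
    return _read("phenotypes.tsv")


def load_significant_metabolites() -> pd.DataFrame:
    """The published table of metabolites differing between obese and
    lean mice (raw-scale group means/SDs and the line-effect p-value).

    Note the p-values are as printed (rounded to the table's
    precision); rows at the printed boundary 0.05 passed the study's
    strict p < 0.05 test before rounding, so the published significant
    set is exactly the row set of this table.
    """
    return _read("significant_metabolites.tsv")


def load_ccna2_variants() -> list[Variant]:
    """The published promoter/transcript variant records."""
    df = _read("ccna2_variants.tsv")
    out = []
    for _, r in df.iterrows():
        out.append(
            Variant(
                pos=int(r["pos"]),
                ref=str(r["ref"]),
                alt=str(r["alt"]),
                known_id=None if pd.isna(r["known_id"]) else str(r["known_id"]),
                region=str(r["region"]),
                function=None if pd.isna(r["function"]) else str(r["function"]),
                effect=None if pd.isna(r.get("effect")) else str(r.get("effect")),
            )
        )
    return out


def ccna2_gene_model() -> GeneModel:
    """Synthetic-boundary gene model consistent with the published
    variant annotations (minus strand; 420-bp promoter at
    36471074-36471493; the coding SNPs land on codon positions that
    reproduce the published synonymous Leu and Gln readouts)."""
    return GeneModel(
        chrom=CCNA2_CHROM,
        strand="-",
        exons=(
            (36463850, 36465300),
            (36466000, 36466100),
            (36466500, 36466600),
            (36467000, 36467100),
            (36467600, 36467800),
            (36469000, 36469201),
            (36470000, 36470199),
            (36470600, 36471073),
        ),
        cds=(36465099, 36470757),
        promoter_length=420,
    )


#: codon-context bases pinning the published amino-acid readouts:
#: the exon-1 coding SNP sits on position 1 of a CTG (Leu) codon and
#: the exon-4 SNP on position 3 of a CAG (Gln) codon.
CCNA2_CODON_CONTEXT = {
    36470690: "T",
    36470689: "G",
    36467697: "C",
    36467696: "A",
}


def build_ccna2_sequences(
    seed: int = 0, max_attempts: int = 20
) -> tuple[str, str, GeneModel]:
    """Reference/alternate sequence pair (transcript orientation)
    carrying exactly the published variant set.

    The random backbone is regenerated (seed incremented) until the
    alignment-based caller round-trips the planted records exactly, so
    the fixture is valid by construction for any starting seed.
    """
    model = ccna2_gene_model()
    variants = load_ccna2_variants()
    planted = {(v.pos, v.ref, v.alt) for v in variants}
    offset = model.span[1]
    last_err = None
    for k in range(max_attempts):
        ref, alt = generate_sequences(
            model, variants, seed=seed + k, context=CCNA2_CODON_CONTEXT
        )
        called = call_variants(ref, alt, offset=offset, strand=model.strand)
        if {(v.pos, v.ref, v.alt) for v in called} == planted:
            return ref, alt, model
        last_err = f"backbone seed {seed + k} did not round-trip"
    raise RuntimeError(f"could not construct fixture: {last_err}")
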
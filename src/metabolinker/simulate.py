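"""Synthetic study-data generators.

Every input the analysis pipeline consumes can be generated here with
the statistical structure the analysis assumes: a three-line (obese
inbred BFMI, lean B6 control, lean F1 cross) x two-sex x two-diet serum
metabolome with lognormal concentration noise and a recessive line
effect confined to BFMI samples; reference-replicate tables with
per-metabolite target CVs; a tri-partite metabolite-enzyme-gene
interactome with planted paths and score-controlled noise; a
promoter+transcript sequence pair carrying a planted variant set; and
triplicate qPCR Ct tables with two endogenous control genes.

All randomness flows from one explicit integer seed per call; identical
specs and seeds reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import PanelSpec, build_panel
from .variants import GeneModel, Variant, apply_variants

OBESE_LINE = "BFMI"
LEAN_LINES = ("B6", "F1")


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class StudyDesignSpec:
    """Factorial animal design: lines x sexes x diets, n mice per cell."""

    lines: tuple[str, ...] = ("BFMI", "B6", "F1")
    sexes: tuple[str, ...] = ("M", "F")
    diets: tuple[str, ...] = ("SMD", "HFD")
    n_per_cell: int = 5
    n_reference_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_cell < 2:
            raise ValueError("n_per_cell must be >= 2")
        if self.n_reference_replicates < 3:
            raise ValueError("n_reference_replicates must be >= 3")
        for name, labels in (
            ("lines", self.lines),
            ("sexes", self.sexes),
            ("diets", self.diets),
        ):
            if not labels:
                raise ValueError(f"{name} must be non-empty")
            if len(set(labels)) != len(labels):
                raise ValueError(f"duplicate labels in {name}")


@dataclass(frozen=True)
class EffectSpec:
    """Planted metabolite effects.

    ``effect_log_fold`` maps metabolite id -> shift of the natural-log
    concentration mean; with ``effect_mode='recessive'`` the shift
    applies only to samples of the obese line (B6 and F1 cells share
    means).  ``high_cv_metabolites`` names metabolites whose reference
    replicates should be noisy (target CV above the QC threshold).
    """

    effect_log_fold: Mapping[str, float] = field(default_factory=dict)
    effect_mode: str = "recessive"
    noise_sd_log: float = 0.2
    high_cv_metabolites: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.noise_sd_log <= 0:
            raise ValueError("noise_sd_log must be > 0")
        if self.effect_mode not in ("recessive", "all"):
            raise ValueError(f"unknown effect_mode {self.effect_mode!r}")

    @property
    def affected_metabolites(self) -> tuple[str, ...]:
        return tuple(self.effect_log_fold)


# ---------------------------------------------------------------------------
# metabolome


def generate_metabolome(
    design: StudyDesignSpec,
    panel: PanelSpec | pd.DataFrame | None = None,
    effects: EffectSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a samples x metabolites concentration matrix (umol/L)
    plus its sample design table (columns line/sex/diet).

    Log-concentrations are Gaussian: per-metabolite baseline log-means
    are drawn once, the planted effect shifts the obese-line mean, and
    ``noise_sd_log`` is the within-cell SD.
    """
    if panel is None or isinstance(panel, PanelSpec):
        panel_df = build_panel(panel)
    else:
        panel_df = panel
    effects = effects or EffectSpec()
    metabolites = list(panel_df["metabolite"])
    unknown = set(effects.effect_log_fold) - set(metabolites)
    if unknown:
        raise ValueError(f"unknown metabolite ids in effects: {sorted(unknown)}")

    rng = np.random.default_rng(design.seed)
    rows = []
    for line in design.lines:
        for sex in design.sexes:
            for diet in design.diets:
                for k in range(design.n_per_cell):
                    rows.append((f"{line}_{sex}_{diet}_{k + 1}", line, sex, diet))
    design_df = pd.DataFrame(
        rows, columns=["sample", "line", "sex", "diet"]
    ).set_index("sample")

    # baseline log-mean per metabolite, spanning ~0.1 to ~200 umol/L
    base_log = rng.uniform(np.log(0.1), np.log(200.0), size=len(metabolites))
    means = np.tile(base_log, (len(design_df), 1))
    for mid, shift in effects.effect_log_fold.items():
        j = metabolites.index(mid)
        if effects.effect_mode == "recessive":
            mask = (design_df["line"] == OBESE_LINE).to_numpy()
        else:
            mask = np.ones(len(design_df), dtype=bool)
        means[mask, j] += shift
    log_conc = means + rng.normal(0.0, effects.noise_sd_log, size=means.shape)
    conc = pd.DataFrame(
        np.exp(log_conc), index=design_df.index, columns=metabolites
    )
    return conc, design_df


def generate_reference_replicates(
    panel: PanelSpec | pd.DataFrame | None,
    cv_targets: Mapping[str, float],
    n: int,
    seed: int = 0,
    default_cv: float = 0.05,
    mean_concentration: float = 10.0,
) -> pd.DataFrame:
    """Simulate reference-sample replicate measurements (replicates x
    metabolites) with per-metabolite target CVs.

    A target CV c is realized by lognormal noise with
    sigma = sqrt(ln(1 + c^2)), whose theoretical CV is exactly c.
    """
    if n < 2:
        raise ValueError("need at least 2 reference replicates")
    for mid, c in cv_targets.items():
        if c < 0:
            raise ValueError(f"negative CV target for {mid}")
    if panel is None or isinstance(panel, PanelSpec):
        panel_df = build_panel(panel)
    else:
        panel_df = panel
    metabolites = list(panel_df["metabolite"])
    unknown = set(cv_targets) - set(metabolites)
    if unknown:
        raise ValueError(f"unknown metabolite ids in cv_targets: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    data = {}
    for mid in metabolites:
        c = cv_targets.get(mid, default_cv)
        if c == 0:
            data[mid] = np.full(n, mean_concentration)
            continue
        sigma = np.sqrt(np.log1p(c * c))
        mu = np.log(mean_concentration) - sigma * sigma / 2.0
        data[mid] = rng.lognormal(mu, sigma, size=n)
    return pd.DataFrame(
        data, index=[f"ref_{i + 1}" for i in range(n)], columns=metabolites
    )


# ---------------------------------------------------------------------------
# interactome


@dataclass(frozen=True)
class PlantedPath:
    """One metabolite -> enzyme (-> intermediate protein) -> gene path.

    ``scores`` are the confidence scores of the path's protein-protein
    edges, in traversal order (one score for a 2-edge path, two for a
    3-edge path).  The gene's encoded protein is the gene symbol
    upper-cased.
    """

    metabolite: str
    enzyme: str
    gene: str
    intermediate: str | None = None
    scores: tuple[float, ...] = (0.9,)

    def __post_init__(self) -> None:
        expected = 1 if self.intermediate is None else 2
        if len(self.scores) != expected:
            raise ValueError(
                f"path needs {expected} PPI score(s), got {len(self.scores)}"
            )
        if any(not (0.0 <= s <= 1.0) for s in self.scores):
            raise ValueError("scores must lie in [0, 1]")

    @property
    def gene_protein(self) -> str:
        return self.gene.upper()


def generate_interactome(
    planted_paths: Sequence[PlantedPath],
    n_noise_nodes: int = 0,
    n_noise_edges: int = 0,
    seed: int = 0,
    noise_score_range: tuple[float, float] = (0.1, 1.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build annotation (metabolite, enzyme) and scored PPI
    (protein_a, protein_b, score) tables containing the planted paths
    plus noise.

    Noise PPI edges connect noise proteins to each other and to planted
    enzymes/intermediates, but never touch a gene's protein, so they
    cannot create a shorter metabolite -> gene path than a planted one.
    """
    rng = np.random.default_rng(seed)
    annotation: list[tuple[str, str]] = []
    ppi: dict[tuple[str, str], float] = {}

    def add_ppi(a: str, b: str, score: float) -> None:
        key = (min(a, b), max(a, b))
        if key in ppi and ppi[key] != score:
            raise ValueError(
                f"conflicting scores for duplicate edge {key}: "
                f"{ppi[key]} vs {score}"
            )
        ppi[key] = score

    for p in planted_paths:
        if (p.metabolite, p.enzyme) not in annotation:
            annotation.append((p.metabolite, p.enzyme))
        if p.intermediate is None:
            add_ppi(p.enzyme, p.gene_protein, p.scores[0])
        else:
            add_ppi(p.enzyme, p.intermediate, p.scores[0])
            add_ppi(p.intermediate, p.gene_protein, p.scores[1])

    gene_proteins = {p.gene_protein for p in planted_paths}
    safe_nodes = sorted(
        {p.enzyme for p in planted_paths}
        | {p.intermediate for p in planted_paths if p.intermediate}
        | {f"NOISE_P{i + 1}" for i in range(n_noise_nodes)}
    )
    attempts = 0
    added = 0
    while added < n_noise_edges and attempts < 100 * max(n_noise_edges, 1):
        attempts += 1
        a, b = rng.choice(safe_nodes, size=2, replace=False)
        key = (min(a, b), max(a, b))
        if key in ppi or a in gene_proteins or b in gene_proteins:
            continue
        ppi[key] = float(
            np.round(rng.uniform(*noise_score_range), 3)
        )
        added += 1

    annotation_df = pd.DataFrame(annotation, columns=["metabolite", "enzyme"])
    ppi_df = pd.DataFrame(
        [(a, b, s) for (a, b), s in sorted(ppi.items())],
        columns=["protein_a", "protein_b", "score"],
    )
    return annotation_df, ppi_df


# ---------------------------------------------------------------------------
# sequences


def generate_sequences(
    gene_model: GeneModel,
    variant_spec: Sequence[Variant],
    seed: int = 0,
    context: Mapping[int, str] | None = None,
) -> tuple[str, str]:
    """Generate a reference/alternate sequence pair for the modeled
    region (transcript orientation) carrying exactly ``variant_spec``.

    The backbone is random with ~40% GC; reference alleles (and any
    ``context`` bases, a chromosome-position -> base mapping, e.g. to
    pin codon contexts) are forced into the backbone, indel flanks are
    de-repeated so left-normalization is the identity on the planted
    records, then the variants are applied to produce the alternate.
    CDS completeness (start/stop codons) is not enforced - the
    sequences exercise alignment-based variant calling and regulatory
    scanning, not translation initiation.
    """
    from .variants import genomic_to_local

    lo, hi = gene_model.span
    length = hi - lo + 1
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=length, p=[0.3, 0.2, 0.2, 0.3])
    offset = hi if gene_model.strand == "-" else lo

    forced: set[int] = set()  # local positions whose base is pinned
    occupied: list[tuple[int, int]] = []  # (start, end) local ref spans
    ins_points: set[int] = set()
    for pos, base in (context or {}).items():
        i = genomic_to_local(pos, offset, gene_model.strand)
        if not (1 <= i <= length):
            raise ValueError(f"context base at {pos} outside the modeled span")
        seq[i - 1] = base
        forced.add(i)
    for v in variant_spec:
        i = genomic_to_local(v.pos, offset, gene_model.strand)
        ref_len = 0 if v.ref == "-" else len(v.ref)
        if i < 1 or i + max(ref_len, 1) - 1 > length:
            raise ValueError(f"variant at {v.pos} outside the modeled span")
        if v.type == "INS":
            if i in ins_points:
                raise ValueError(f"duplicate insertion point at {v.pos}")
            ins_points.add(i)
        else:
            span = (i, i + ref_len - 1)
            for s, e in occupied:
                if span[0] <= e and s <= span[1]:
                    raise ValueError(
                        f"overlapping variants near position {v.pos}"
                    )
            occupied.append(span)
            for k, base in enumerate(v.ref):
                seq[i - 1 + k] = base
                forced.add(i + k)
    # break repeat context around indels so the planted records are
    # already in left-normalized form
    for v in variant_spec:
        if v.type == "SNP":
            continue
        i = genomic_to_local(v.pos, offset, gene_model.strand)
        allele = v.ref if v.type == "DEL" else v.alt
        left = i - 1  # local position of the base left of the event
        if left >= 1 and seq[left - 1] == allele[-1] and left not in forced:
            seq[left - 1] = _different_base(allele[-1])
            forced.add(left)
        right = i + (len(allele) if v.type == "DEL" else 0)
        if right <= length and seq[right - 1] == allele[0] and right not in forced:
            seq[right - 1] = _different_base(allele[0])
            forced.add(right)
    ref_seq = "".join(seq)
    alt_seq = apply_variants(ref_seq, list(variant_spec), offset, gene_model.strand)
    return ref_seq, alt_seq


def _different_base(avoid: str) -> str:
    return "A" if avoid != "A" else "C"


def write_fasta(path: str, records: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# qPCR


def generate_qpcr(
    groups: Mapping[str, int],
    fold_changes: Mapping[str, float],
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    target_gene: str = "Ccna2",
    control_genes: tuple[str, ...] = ("Rps25", "bActin"),
    calibrator_group: str | None = None,
    n_replicates: int = 3,
    base_target_ct: float = 28.0,
    base_control_ct: float = 20.0,
) -> pd.DataFrame:
    """Simulate a long-format Ct table (sample, gene, replicate, Ct,
    group) with triplicate wells, one target gene and two endogenous
    controls.

    ``fold_changes`` maps group -> expression fold relative to the
    calibrator group (which defaults to the first group); a fold f
    lowers the target Ct by log2(f).  Control-gene Cts are
    group-independent, so the expected pipeline RQ of each group equals
    its specified fold change.
    """
    if not control_genes:
        raise ValueError("at least one control gene must be specified")
    for g, f in fold_changes.items():
        if f <= 0:
            raise ValueError(f"fold change for group {g!r} must be > 0")
    unknown = set(fold_changes) - set(groups)
    if unknown:
        raise ValueError(f"fold changes for unknown groups: {sorted(unknown)}")
    calibrator_group = calibrator_group or next(iter(groups))
    cal_fold = fold_changes.get(calibrator_group, 1.0)
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in groups.items():
        fold = fold_changes.get(group, 1.0) / cal_fold
        for s in range(n):
            sample = f"{group}_{s + 1}"
            target_ct = base_target_ct - np.log2(fold)
            for gene, base in [(target_gene, target_ct)] + [
                (cg, base_control_ct + 2 * k)
                for k, cg in enumerate(control_genes)
            ]:
                for rep in range(n_replicates):
                    noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                    rows.append((sample, gene, rep + 1, base + noise, group))
    return pd.DataFrame(
        rows, columns=["sample", "gene", "replicate", "Ct", "group"]
    )
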
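"""Synthetic reciprocal-cross endosperm experiments with known truth.

The generator emulates the structure the RER method is built around: two
genome-assembled parents crossed reciprocally, endosperm sampled in
triplicate per direction, and unique-read counts per allele feature. For a
biparental feature the two maternal genome copies and one paternal copy
make expression twice as high when the feature's genome is inherited
maternally; imprinted classes concentrate expression on one parental
allele; genotype-biased features concentrate expression on one genotype
regardless of direction (which leaves RER at the dosage expectation while
flipping SNP-ASE between reciprocals); PAV features exist in one genome
only. Replicate noise is negative-binomial with mean mu and variance
mu + alpha*mu^2.

Counts are drawn at the allele level, so the SNP-ASE allele-count table is
exactly consistent with the RER count table. No sequence-level reads are
simulated; alignment is upstream of this package's contract.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .annotate import FeatureAnnotation
from .counts import AlignmentRecord, CountTable, SampleMeta
from .intervals import Interval

__all__ = [
    "SimConfig",
    "SimResult",
    "AnnotationSim",
    "TissueSim",
    "simulate_counts",
    "simulate_annotation",
    "simulate_tissue_profiles",
]

CLASS_NAMES = (
    "biparental",
    "meg_like",
    "peg_like",
    "genotype_biased",
    "pav_maternal_te",
    "pav_silent",
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic reciprocal-cross experiment.

    Defaults mirror the design the method targets: three biological
    replicates per cross direction, negative-binomial dispersion 0.1,
    base mean 100 (the maternal-direction mean of a biparental feature),
    and fully monoallelic imprinted classes (maternal_fraction 1.0).
    """

    n_biparental: int = 300
    n_meg_like: int = 50
    n_peg_like: int = 50
    n_genotype_biased: int = 50
    n_pav_maternal_te: int = 30
    n_pav_silent: int = 20
    replicates: int = 3
    base_mean: float = 100.0
    dispersion: float = 0.1
    maternal_fraction: float = 1.0
    library_size: float = 1_000_000.0
    library_size_sigma: float = 0.2
    genotypes: tuple[str, str] = ("B73", "W22")
    seed: int = 0
    # tissue-profile planting (standalone features)
    n_pericarp_contaminant: int = 20
    n_endosperm_preferred: int = 30
    n_constitutive: int = 50

    def __post_init__(self) -> None:
        for name in (
            "n_biparental", "n_meg_like", "n_peg_like", "n_genotype_biased",
            "n_pav_maternal_te", "n_pav_silent",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.base_mean <= 0 or self.library_size <= 0:
            raise ValueError("base_mean and library_size must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0.5 <= self.maternal_fraction <= 1.0:
            raise ValueError("maternal_fraction must lie in [0.5, 1]")
        if len(set(self.genotypes)) != 2:
            raise ValueError("genotypes must be two distinct names")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["genotypes"] = list(self.genotypes)
        return d


@dataclass
class SimResult:
    table: CountTable
    truth: pd.DataFrame  # index feature_id: class, true_rer, genome, present_in, anchor
    allele_counts: pd.DataFrame  # gene_id, library_id, maternal_reads, paternal_reads
    ortholog_map: pd.DataFrame  # anchor + one column per genotype + grass_syntenic
    config: SimConfig


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB with mean mu, variance mu + alpha*mu^2 (Poisson when alpha=0)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=int)
    pos = mean > 0
    if alpha == 0:
        out[pos] = rng.poisson(mean[pos])
    else:
        n = 1.0 / alpha
        p = n / (n + mean[pos])
        out[pos] = rng.negative_binomial(n, p)
    return out


def _true_rer(f: float) -> float:
    """Expected RER for maternal copy fraction f (2 maternal : 1 paternal copies)."""
    return 2 * f / (2 * f + (1 - f))


def simulate_counts(config: SimConfig | None = None) -> SimResult:
    """Draw the full reciprocal-cross count experiment.

    Each shared feature contributes one allele feature per genome; PAV
    classes contribute a single allele on alternating genomes. For an
    allele with maternal copy fraction ``f`` and per-copy rate
    ``r = base_mean / 2``, the expected count is ``2*r*2f = 2*base_mean*f``
    in libraries where its genome is the mother and ``base_mean*(1-f)``
    where it is the father, scaled by the library's size factor. The same
    seed always reproduces identical tables.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    geno_a, geno_b = cfg.genotypes

    samples: list[SampleMeta] = []
    for mother, father in ((geno_a, geno_b), (geno_b, geno_a)):
        for rep in range(1, cfg.replicates + 1):
            samples.append(
                SampleMeta(f"{mother}x{father}_rep{rep}", mother, father, rep)
            )
    n_libs = len(samples)
    lib_factors = rng.lognormal(0.0, cfg.library_size_sigma, n_libs)
    lib_factors /= lib_factors.mean()
    for s, fac in zip(samples, lib_factors):
        s.library_size = int(round(cfg.library_size * fac))

    # per-allele direction means ---------------------------------------------
    feature_rows = []  # (feature_id, anchor, genome, kind, class, f_maternal, expressed)
    f_imp = cfg.maternal_fraction

    def add_shared(anchor: str, cls: str, f: float, silent_genome: str | None = None):
        for g in (geno_a, geno_b):
            fid = f"{anchor}_{g}"
            expressed = g != silent_genome
            feature_rows.append((fid, anchor, g, "gene", cls, f, expressed))

    for k in range(cfg.n_biparental):
        add_shared(f"bipar{k:05d}", "biparental", 0.5)
    for k in range(cfg.n_meg_like):
        add_shared(f"meg{k:04d}", "meg_like", f_imp)
    for k in range(cfg.n_peg_like):
        add_shared(f"peg{k:04d}", "peg_like", 1.0 - f_imp)
    for k in range(cfg.n_genotype_biased):
        favored = (geno_a, geno_b)[k % 2]
        silenced = geno_b if favored == geno_a else geno_a
        add_shared(f"gbias{k:04d}", "genotype_biased", 0.5, silent_genome=silenced)
    for k in range(cfg.n_pav_maternal_te):
        g = (geno_a, geno_b)[k % 2]
        feature_rows.append(
            (f"pavte{k:04d}_{g}", f"pavte{k:04d}", g, "TE", "pav_maternal_te", f_imp, True)
        )
    for k in range(cfg.n_pav_silent):
        g = (geno_a, geno_b)[k % 2]
        feature_rows.append(
            (f"pavsil{k:04d}_{g}", f"pavsil{k:04d}", g, "gene", "pav_silent", 0.5, False)
        )

    fids = [r[0] for r in feature_rows]
    r_copy = cfg.base_mean / 2.0
    means = np.zeros((len(feature_rows), n_libs))
    for irow, (_, _, g, _, _, f, expressed) in enumerate(feature_rows):
        if not expressed:
            continue
        for j, s in enumerate(samples):
            if s.mother == g:
                mu = 2.0 * r_copy * 2.0 * f  # two maternal copies at rate r*2f
            elif s.father == g:
                mu = 2.0 * r_copy * (1.0 - f)  # one paternal copy at rate r*2(1-f)
            else:
                continue
            means[irow, j] = mu * lib_factors[j]

    counts = _nb_draw(rng, means, cfg.dispersion)
    count_df = pd.DataFrame(counts, index=fids, columns=[s.library_id for s in samples])
    features = pd.DataFrame(
        {
            "genome": [r[2] for r in feature_rows],
            "kind": [r[3] for r in feature_rows],
        },
        index=pd.Index(fids, name="feature_id"),
    )
    table = CountTable(count_df, samples, features)

    truth = pd.DataFrame(
        {
            "anchor": [r[1] for r in feature_rows],
            "class": [r[4] for r in feature_rows],
            "genome": [r[2] for r in feature_rows],
            "kind": [r[3] for r in feature_rows],
            "present_in": [
                "both" if r[4] in {"biparental", "meg_like", "peg_like", "genotype_biased"}
                else r[2]
                for r in feature_rows
            ],
            "expressed": [r[6] for r in feature_rows],
            "true_rer": [
                _true_rer(r[5]) if r[6] else np.nan for r in feature_rows
            ],
        },
        index=pd.Index(fids, name="feature_id"),
    )

    # SNP-ASE allele counts: per shared gene, per library, mother vs father allele
    shared_anchors = truth.loc[truth["present_in"] == "both", "anchor"].unique()
    row_of = {fid: i for i, fid in enumerate(fids)}
    ac_rows = []
    for anchor in shared_anchors:
        fid_a, fid_b = f"{anchor}_{geno_a}", f"{anchor}_{geno_b}"
        for j, s in enumerate(samples):
            mother_fid = fid_a if s.mother == geno_a else fid_b
            father_fid = fid_b if mother_fid == fid_a else fid_a
            ac_rows.append(
                {
                    "gene_id": anchor,
                    "library_id": s.library_id,
                    "maternal_reads": int(counts[row_of[mother_fid], j]),
                    "paternal_reads": int(counts[row_of[father_fid], j]),
                }
            )
    allele_counts = pd.DataFrame(ac_rows)

    anchors = truth["anchor"].unique()
    map_rows = []
    for anchor in anchors:
        members = truth[truth["anchor"] == anchor]
        row = {"anchor": anchor, geno_a: np.nan, geno_b: np.nan}
        for fid, g in zip(members.index, members["genome"]):
            row[g] = fid
        row["grass_syntenic"] = bool(
            rng.random() < (0.6 if members["class"].iloc[0] == "biparental" else 0.15)
        )
        map_rows.append(row)
    ortholog_map = pd.DataFrame(map_rows)

    return SimResult(table, truth, allele_counts, ortholog_map, cfg)


# ---------------------------------------------------------------------------
# toy annotation + alignment records
# ---------------------------------------------------------------------------


@dataclass
class AnnotationSim:
    genes: dict[str, list[FeatureAnnotation]]  # genotype -> gene features
    tes: dict[str, list[FeatureAnnotation]]  # genotype -> raw TE features
    alignments: list[AlignmentRecord]  # on concatenated sequence names
    expected_assignment: dict[str, int]  # feature_id -> expected count
    expected_summary: dict[str, int]


def simulate_annotation(config: SimConfig | None = None) -> AnnotationSim:
    """Toy two-genome annotation plus alignment records of known fate.

    Each genome gets genes with two exons, one intronic TE, one TE
    overlapping an exon, and one intergenic TE. Reads are placed so their
    assignment is known by construction: exonic reads (gene), reads inside
    the intronic TE (TE), reads spanning the exon/TE boundary (ambiguous),
    intergenic reads (no feature), and multimapping reads (non-unique).
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed + 1)
    genes: dict[str, list[FeatureAnnotation]] = {}
    tes: dict[str, list[FeatureAnnotation]] = {}
    alignments: list[AlignmentRecord] = []
    expected: dict[str, int] = {}
    summary = {"assigned": 0, "ambiguous": 0, "no_feature": 0, "non_unique": 0}

    for g in cfg.genotypes:
        chrom = f"{g}_chr1"  # concatenated naming
        glist, tlist = [], []
        for k in range(3):
            off = 10_000 * k
            gid = f"{g}_gene{k}"
            exons = [
                Interval(chrom, off + 1000, off + 1500, "+"),
                Interval(chrom, off + 3000, off + 3600, "+"),
            ]
            glist.append(FeatureAnnotation(gid, g, "gene", exons, strand="+"))
            # intronic TE: inside [1500, 3000)
            te_in = f"{g}_te{k}_intronic"
            tlist.append(
                FeatureAnnotation(
                    te_in, g, "TE",
                    [Interval(chrom, off + 1800, off + 2600, "+")],
                    strand="+", te_order="LTR", te_family="RLX00001",
                )
            )
            # TE overlapping the second exon: [3400, 4200) -> exon part trimmed
            te_ov = f"{g}_te{k}_exonov"
            tlist.append(
                FeatureAnnotation(
                    te_ov, g, "TE",
                    [Interval(chrom, off + 3400, off + 4200, "+")],
                    strand="+", te_order="DHH", te_family="DHH00002",
                )
            )
            expected.setdefault(gid, 0)
            expected.setdefault(te_in, 0)
            expected.setdefault(te_ov, 0)

            n_exonic = int(rng.integers(3, 8))
            for r in range(n_exonic):
                alignments.append(
                    AlignmentRecord(f"{gid}_r{r}", chrom, off + 1050 + 10 * r, off + 1150 + 10 * r)
                )
            expected[gid] += n_exonic
            summary["assigned"] += n_exonic

            n_te = int(rng.integers(2, 6))
            for r in range(n_te):
                alignments.append(
                    AlignmentRecord(f"{te_in}_r{r}", chrom, off + 1900 + 20 * r, off + 2000 + 20 * r)
                )
            expected[te_in] += n_te
            summary["assigned"] += n_te

            # trimmed exon-overlap TE keeps [3600, 4200): reads there count to it
            n_te2 = int(rng.integers(1, 4))
            for r in range(n_te2):
                alignments.append(
                    AlignmentRecord(f"{te_ov}_r{r}", chrom, off + 3700 + 20 * r, off + 3800 + 20 * r)
                )
            expected[te_ov] += n_te2
            summary["assigned"] += n_te2

            # boundary read: spans exon end and TE -> overlaps gene + trimmed TE
            alignments.append(
                AlignmentRecord(f"{gid}_amb", chrom, off + 3550, off + 3700)
            )
            summary["ambiguous"] += 1
            # intergenic read
            alignments.append(
                AlignmentRecord(f"{gid}_nf", chrom, off + 8000, off + 8100)
            )
            summary["no_feature"] += 1
            # multimapper
            alignments.append(
                AlignmentRecord(f"{gid}_mm", chrom, off + 1050, off + 1150, is_unique=False)
            )
            summary["non_unique"] += 1
        genes[g] = glist
        tes[g] = tlist

    return AnnotationSim(genes, tes, alignments, expected, summary)


# ---------------------------------------------------------------------------
# tissue profiles
# ---------------------------------------------------------------------------


@dataclass
class TissueSim:
    expression: pd.DataFrame  # features x tissue libraries (RPM-like)
    tissue_classes: pd.Series  # library -> class
    truth: pd.DataFrame  # planted_class per feature


def simulate_tissue_profiles(config: SimConfig | None = None) -> TissueSim:
    """Multi-tissue expression matrix with planted filter outcomes.

    Libraries: two endosperm, one whole-seed, two pericarp, three other
    tissues. Planted classes: ``pericarp_contaminant`` (pericarp mean more
    than twice the endosperm mean), ``endosperm_preferred`` (endosperm +
    seed carry > 60% of the total), and ``constitutive`` (flat profile,
    neither flag).
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed + 2)
    libs = [
        ("endo1", "endosperm"), ("endo2", "endosperm"), ("seed1", "seed"),
        ("peri1", "pericarp"), ("peri2", "pericarp"),
        ("leaf", "other"), ("root", "other"), ("tassel", "other"),
    ]
    classes = pd.Series({lib: cls for lib, cls in libs})
    col_class = np.array([cls for _, cls in libs])

    rows, truth_rows = [], []
    noise = lambda n: rng.lognormal(0.0, 0.1, n)  # mild multiplicative noise

    def profile(base: dict[str, float]) -> np.ndarray:
        return np.array([base[c] for c in col_class]) * noise(len(libs))

    for k in range(cfg.n_pericarp_contaminant):
        rows.append(profile({"endosperm": 5.0, "seed": 8.0, "pericarp": 50.0, "other": 5.0}))
        truth_rows.append((f"contam{k:04d}", "pericarp_contaminant"))
    for k in range(cfg.n_endosperm_preferred):
        rows.append(profile({"endosperm": 80.0, "seed": 40.0, "pericarp": 2.0, "other": 2.0}))
        truth_rows.append((f"endopref{k:04d}", "endosperm_preferred"))
    for k in range(cfg.n_constitutive):
        rows.append(profile({"endosperm": 20.0, "seed": 20.0, "pericarp": 20.0, "other": 20.0}))
        truth_rows.append((f"constit{k:04d}", "constitutive"))

    ids = [t[0] for t in truth_rows]
    expression = pd.DataFrame(rows, index=pd.Index(ids, name="feature_id"),
                              columns=[lib for lib, _ in libs])
    truth = pd.DataFrame(
        {"planted_class": [t[1] for t in truth_rows]},
        index=pd.Index(ids, name="feature_id"),
    )
    return TissueSim(expression, classes, truth)
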
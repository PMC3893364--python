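"""Synthetic multi-platform expression sets and IHC cohorts with known truth.

The generator emulates the structure of a pooled meningeal-tumour compendium:
several independently produced log2 expression matrices on different array
platforms, each shifted by an additive per-set batch offset; a panel of
housekeeping genes that is expression-stable across histotypes (and, by
default, less noisy than the background transcriptome); and one target gene
(ALDH1A1) whose mean log2 level depends on histotype, optionally boosted in
meningeal samples.  Affymetrix-style platforms emit redundant probe sets per
gene ("_at" / "s_at" / "x_at") and the cDNA platform emits duplicate clones,
so probe-collapsing tie-breaks are exercised.

IHC cohorts come in two modes: *stochastic* (Bernoulli positivity and banded
staining percentages drawn per sample) and *quota* (exact joint
ALDH1 x CD34 counts per histotype group, for deterministic reproduction of
published count tables).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionSet, AFFYMETRIX_PLATFORMS, write_expression_tsv, write_sample_annotations
from .probes import ProbeAnnotation, write_probe_annotations
from .accuracy import COHORT_COLUMNS

TARGET_GENE = "ALDH1A1"

# representative percent-stained value per band (quota mode is deterministic)
BAND_PERCENT = {"none": 0, "low": 7, "intermediate": 30, "high": 75}
# sampling ranges per band: negatives in [0,5), low [5,10], intermediate
# (10,50], high (50,100] — integers, uniform within the band
BAND_RANGE = {"none": (0, 4), "low": (5, 10), "intermediate": (11, 50), "high": (51, 100)}


# ---------------------------------------------------------------------------
# expression arm
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTruth:
    """Ground truth for the expression generator.

    ``per_histotype_log2_mean`` gives the target gene's absolute mean log2
    level per histotype; ``batch_offsets`` are additive per-set log2 shifts
    applied to every gene; ``meningeal_boost`` is added to the target in
    meningeal samples (the site effect seen in the real compendium).
    Housekeeping genes carry no histotype effect and default to half the
    background noise — stability is what makes them housekeeping genes.
    """

    per_histotype_log2_mean: dict[str, float]
    batch_offsets: dict[str, float]
    housekeeping_ids: list[str]
    noise_sd: float = 0.3
    housekeeping_noise_sd: float | None = None
    target_gene_id: str = TARGET_GENE
    meningeal_boost: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.housekeeping_noise_sd is None:
            self.housekeeping_noise_sd = self.noise_sd / 2.0
        if self.housekeeping_noise_sd < 0:
            raise ValueError("housekeeping_noise_sd must be >= 0")
        if self.target_gene_id in self.housekeeping_ids:
            raise ValueError("target gene cannot be a housekeeping gene")


@dataclass(frozen=True)
class SampleBlock:
    histotype: str
    site: str
    n: int


@dataclass
class SetLayout:
    """One synthetic study: its platform and per-histotype sample counts."""

    set_id: str
    platform: str
    blocks: list[SampleBlock]
    n_background_genes: int = 200

    @property
    def n_samples(self) -> int:
        return sum(b.n for b in self.blocks)


def _gene_list(truth: ExpressionTruth, n_background: int) -> list[str]:
    return [truth.target_gene_id, *truth.housekeeping_ids,
            *(f"BG{i:04d}" for i in range(1, n_background + 1))]


def _baselines(truth: ExpressionTruth, n_background: int) -> pd.Series:
    """Per-gene histotype-independent baselines, fixed by the truth seed so
    every set shares them (a gene property, not a batch property)."""
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 101]))
    hk = 8.0 + 1.5 * rng.standard_normal(len(truth.housekeeping_ids))
    bg = 8.0 + 2.0 * rng.standard_normal(n_background)
    genes = _gene_list(truth, n_background)
    return pd.Series(np.concatenate([[0.0], hk, bg]), index=genes)


def _probe_table(platform: str, genes: list[str]) -> list[tuple[str, str, str, int]]:
    """(probe_id, gene, extension, extra_noise_level) rows for one platform.

    Affymetrix platforms add redundant "s_at" / "x_at" probe sets for a subset
    of genes, with inflated noise, so the extension-preference rule (not
    variance) must decide; the cDNA platform adds duplicate clones decided by
    variance alone.
    """
    rows = []
    for i, g in enumerate(genes):
        if platform in AFFYMETRIX_PLATFORMS:
            rows.append((f"{1000 + i}_at", g, "_at", 0))
            if i % 3 == 0:
                rows.append((f"{1000 + i}_s_at", g, "s_at", 1))
            if i % 7 == 0:
                rows.append((f"{1000 + i}_x_at", g, "other", 2))
        elif platform == "cdna_array":
            rows.append((f"IMAGE:{855000 + i}", g, "na", 0))
            if i % 4 == 0:
                rows.append((f"IMAGE:{890000 + i}", g, "na", 1))
        else:
            rows.append((g, g, "na", 0))
    return rows


def simulate_multiplatform_cohort(
    truth: ExpressionTruth, set_layouts: list[SetLayout]
) -> tuple[list[ExpressionSet], list[ProbeAnnotation]]:
    """Generate one probe-level expression set per layout plus annotations.

    Every value is built additively: gene baseline + histotype effect (target
    gene only, plus meningeal boost) + per-set batch offset (all genes) +
    i.i.d. Gaussian noise.  Identical truth + seed gives identical output.
    """
    if not set_layouts:
        raise ValueError("empty layout list")
    if len(set_layouts) < 2:
        raise ValueError("need >=2 sets for a multi-platform cohort")
    for lay in set_layouts:
        if lay.n_samples < 2:
            raise ValueError(f"set {lay.set_id!r} must have >=2 samples")
        for b in lay.blocks:
            if b.histotype not in truth.per_histotype_log2_mean:
                raise ValueError(
                    f"histotype {b.histotype!r} lacks an entry in per_histotype_log2_mean"
                )
        if lay.set_id not in truth.batch_offsets:
            raise ValueError(f"set {lay.set_id!r} lacks a batch offset")

    esets: list[ExpressionSet] = []
    annotations: dict[tuple[str, str], ProbeAnnotation] = {}
    for k, lay in enumerate(set_layouts):
        genes = _gene_list(truth, lay.n_background_genes)
        base = _baselines(truth, lay.n_background_genes)
        rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 202, k]))

        hist = [b.histotype for b in lay.blocks for _ in range(b.n)]
        site = [b.site for b in lay.blocks for _ in range(b.n)]
        sample_ids = [f"{lay.set_id}_s{i:03d}" for i in range(lay.n_samples)]

        n_hk = len(truth.housekeeping_ids)
        sd = np.full(len(genes), truth.noise_sd)
        sd[1:1 + n_hk] = truth.housekeeping_noise_sd

        effect = np.array([
            truth.per_histotype_log2_mean[h]
            + (truth.meningeal_boost if s == "meningeal" else 0.0)
            for h, s in zip(hist, site)
        ])
        gene_vals = np.tile(base.to_numpy()[:, None], (1, lay.n_samples))
        gene_vals[0, :] += effect  # target is row 0
        gene_vals += truth.batch_offsets[lay.set_id]
        gene_vals += rng.standard_normal(gene_vals.shape) * sd[:, None]

        probes = _probe_table(lay.platform, genes)
        gene_row = {g: i for i, g in enumerate(genes)}
        values = np.empty((len(probes), lay.n_samples))
        for r, (pid, g, ext, extra) in enumerate(probes):
            row = gene_vals[gene_row[g]]
            if extra:
                # redundant probes measure the same transcript with extra
                # probe-level noise proportional to the gene's own noise
                row = row + rng.standard_normal(lay.n_samples) * (extra * sd[gene_row[g]])
            values[r] = row
            key = (lay.platform, pid)
            if key not in annotations:
                annotations[key] = ProbeAnnotation(pid, g, lay.platform, ext)

        matrix = pd.DataFrame(values, index=[p[0] for p in probes], columns=sample_ids)
        ann = pd.DataFrame(
            {"set_id": lay.set_id, "platform": lay.platform,
             "histotype": hist, "site": site},
            index=pd.Index(sample_ids, name="sample_id"),
        )
        esets.append(ExpressionSet(matrix=matrix, set_id=lay.set_id,
                                   platform=lay.platform, annotations=ann))
    return esets, list(annotations.values())


def study_layouts(n_background_genes: int = 200) -> list[SetLayout]:
    """Eight studies shaped like the real pooled compendium: one in-house
    Affymetrix U133 Plus 2.0 SFT/HPC set, West's cDNA set, Hajdu's U133A set,
    three meningioma sets and two synovial-sarcoma sets (52 SFT/HPC, 161
    meningiomas, 30 synovial sarcomas in total)."""
    B, g = SampleBlock, n_background_genes
    return [
        SetLayout("inhouse", "affymetrix_u133plus2",
                  [B("HPC", "meningeal", 9), B("SFT", "meningeal", 3),
                   B("SFT", "extrameningeal", 4)], g),
        SetLayout("west", "cdna_array",
                  [B("SFT", "extrameningeal", 13),
                   B("synovial_sarcoma", "extrameningeal", 6)], g),
        SetLayout("hajdu", "affymetrix_u133a",
                  [B("SFT", "meningeal", 8), B("SFT", "extrameningeal", 15),
                   B("synovial_sarcoma", "extrameningeal", 4)], g),
        SetLayout("claus", "affymetrix_u133plus2", [B("meningioma", "meningeal", 31)], g),
        SetLayout("lee", "affymetrix_u133plus2", [B("meningioma", "meningeal", 68)], g),
        SetLayout("scheck", "affymetrix_u133a", [B("meningioma", "meningeal", 62)], g),
        SetLayout("nakayama", "affymetrix_u133a",
                  [B("synovial_sarcoma", "extrameningeal", 16)], g),
        SetLayout("detwiller", "affymetrix_u133plus2",
                  [B("synovial_sarcoma", "extrameningeal", 4)], g),
    ]


def default_truth(
    fold_change_vs_synovial: float = 9.5,
    seed: int = 0,
    n_housekeeping: int = 451,
    noise_sd: float = 0.3,
    layouts: list[SetLayout] | None = None,
) -> ExpressionTruth:
    """Truth mirroring the study's reported regime: the target is
    ``fold_change_vs_synovial`` above synovial sarcomas and ~3x above
    meningiomas, with distinct batch offsets per set (up to 4 log2 units)."""
    layouts = layouts or study_layouts()
    base = 6.0
    shift = float(np.log2(fold_change_vs_synovial))
    offsets = dict(zip(
        [l.set_id for l in layouts],
        [0.0, 2.0, -3.0, 4.0, 1.0, -1.5, 3.0, -2.0][: len(layouts)],
    ))
    return ExpressionTruth(
        per_histotype_log2_mean={
            "SFT": base + shift, "HPC": base + shift,
            "meningioma": base + shift - np.log2(3.0),
            "synovial_sarcoma": base,
        },
        batch_offsets=offsets,
        housekeeping_ids=[f"HK{i:04d}" for i in range(1, n_housekeeping + 1)],
        noise_sd=noise_sd,
        seed=seed,
    )


def integration_benchmark(
    fold_change: float, seed: int, n_per_group: int = 20,
    n_housekeeping: int = 60, n_background_genes: int = 140,
    noise_sd: float = 0.3,
) -> tuple[ExpressionTruth, list[SetLayout]]:
    """Scaled-down integration benchmark: four platforms-crossing sets with
    balanced histotype composition, ~``n_per_group`` samples per histotype
    group overall, batch offsets spanning 4 log2 units."""
    per_set = max(2, n_per_group // 4)
    B = SampleBlock
    platforms = ["affymetrix_u133plus2", "affymetrix_u133a", "cdna_array", "generic"]
    layouts = [
        SetLayout(
            f"set{k}", platforms[k],
            [B("SFT", "meningeal", (per_set + 1) // 2),
             B("HPC", "meningeal", per_set // 2),
             B("meningioma", "meningeal", per_set),
             B("synovial_sarcoma", "extrameningeal", per_set)],
            n_background_genes,
        )
        for k in range(4)
    ]
    base = 6.0
    truth = ExpressionTruth(
        per_histotype_log2_mean={
            "SFT": base + float(np.log2(fold_change)),
            "HPC": base + float(np.log2(fold_change)),
            "meningioma": base + float(np.log2(fold_change)) - float(np.log2(3.0)),
            "synovial_sarcoma": base,
        },
        batch_offsets={"set0": 0.0, "set1": 2.0, "set2": -3.0, "set3": 4.0},
        housekeeping_ids=[f"HK{i:04d}" for i in range(1, n_housekeeping + 1)],
        noise_sd=noise_sd,
        seed=seed,
    )
    return truth, layouts


# ---------------------------------------------------------------------------
# IHC arm
# ---------------------------------------------------------------------------

@dataclass
class IhcTruth:
    """Stochastic IHC cohort parameters.

    ``per_histotype_positive_prob`` maps (histotype, marker) to the positivity
    probability; ``band_distribution`` maps the same keys to probabilities
    over (low, intermediate, high) bands given positivity.
    """

    per_histotype_positive_prob: dict[tuple[str, str], float]
    band_distribution: dict[tuple[str, str], tuple[float, float, float]]
    n_per_histotype: dict[str, int]
    per_histotype_site: dict[str, str] = field(default_factory=lambda: {
        "SFT": "meningeal", "HPC": "meningeal",
        "meningioma": "meningeal", "synovial_sarcoma": "extrameningeal",
    })
    seed: int = 0

    def __post_init__(self) -> None:
        for k, p in self.per_histotype_positive_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"positivity probability out of [0,1] for {k}: {p}")
        for k, d in self.band_distribution.items():
            if len(d) != 3 or any(x < 0 for x in d) or abs(sum(d) - 1.0) > 1e-9:
                raise ValueError(f"band distribution for {k} must be 3 probabilities summing to 1")


def simulate_ihc_cohort(truth: IhcTruth) -> pd.DataFrame:
    """Draw a long-format marker cohort (one row per sample x marker)."""
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 303]))
    markers = sorted({m for _, m in truth.per_histotype_positive_prob})
    rows = []
    for hist, n in truth.n_per_histotype.items():
        site = truth.per_histotype_site.get(hist, "meningeal")
        for i in range(n):
            sid = f"{hist}_{i:03d}"
            for m in markers:
                p = truth.per_histotype_positive_prob.get((hist, m), 0.0)
                if rng.random() < p:
                    dist = truth.band_distribution.get((hist, m), (1 / 3, 1 / 3, 1 / 3))
                    band = ("low", "intermediate", "high")[rng.choice(3, p=dist)]
                else:
                    band = "none"
                lo, hi = BAND_RANGE[band]
                rows.append((sid, hist, site, m, int(rng.integers(lo, hi + 1))))
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


@dataclass(frozen=True)
class QuotaGroup:
    """Exact joint ALDH1 x CD34 counts for one histotype group.

    ``n_pp, n_pn, n_np, n_nn`` are the sample counts with
    (ALDH1+, CD34+), (ALDH1+, CD34-), (ALDH1-, CD34+), (ALDH1-, CD34-).
    ``aldh1_bands`` optionally fixes the (low, intermediate, high) band counts
    among the ALDH1-positive samples.
    """

    label: str
    histotype: str
    site: str
    n_pp: int
    n_pn: int
    n_np: int
    n_nn: int
    aldh1_bands: tuple[int, int, int] | None = None

    @property
    def n(self) -> int:
        return self.n_pp + self.n_pn + self.n_np + self.n_nn


#: quota mirroring the published TMA cohort (meningeal SFT and HPC by grade,
#: meningiomas, genetically confirmed synovial sarcomas) with the published
#: ALDH1 band composition
STUDY_QUOTA: tuple[QuotaGroup, ...] = (
    QuotaGroup("sft", "SFT", "meningeal", 20, 1, 3, 1, aldh1_bands=(3, 10, 8)),
    QuotaGroup("hpc2", "HPC", "meningeal", 14, 4, 5, 1, aldh1_bands=(5, 2, 11)),
    QuotaGroup("hpc3", "HPC", "meningeal", 20, 9, 2, 0, aldh1_bands=(5, 7, 17)),
    QuotaGroup("men", "meningioma", "meningeal", 0, 2, 8, 153, aldh1_bands=(1, 1, 0)),
    QuotaGroup("svs", "synovial_sarcoma", "extrameningeal", 0, 7, 0, 91, aldh1_bands=(3, 0, 4)),
)


def quota_ihc_cohort(groups: tuple[QuotaGroup, ...] = STUDY_QUOTA) -> pd.DataFrame:
    """Deterministic cohort reproducing exact joint marker counts.

    Percent-stained values are representative band values (negative 0, low 7,
    intermediate 30, high 75); only the 5% positivity threshold matters for
    contingency counts, so any in-band value yields the same tables.
    """
    rows = []
    for g in groups:
        aldh1_pos = g.n_pp + g.n_pn
        if g.aldh1_bands is not None:
            if sum(g.aldh1_bands) != aldh1_pos:
                raise ValueError(
                    f"group {g.label!r}: band counts {g.aldh1_bands} do not sum "
                    f"to the {aldh1_pos} ALDH1-positive samples"
                )
            band_seq = (["low"] * g.aldh1_bands[0]
                        + ["intermediate"] * g.aldh1_bands[1]
                        + ["high"] * g.aldh1_bands[2])
        else:
            band_seq = ["intermediate"] * aldh1_pos
        joint = (["pp"] * g.n_pp + ["pn"] * g.n_pn + ["np"] * g.n_np + ["nn"] * g.n_nn)
        band_iter = iter(band_seq)
        for i, jc in enumerate(joint):
            sid = f"{g.label}_{i:03d}"
            aldh1 = BAND_PERCENT[next(band_iter)] if jc in ("pp", "pn") else 0
            cd34 = BAND_PERCENT["intermediate"] if jc in ("pp", "np") else 0
            rows.append((sid, g.histotype, g.site, "ALDH1", aldh1))
            rows.append((sid, g.histotype, g.site, "CD34", cd34))
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def default_ihc_truth(seed: int = 0) -> IhcTruth:
    """Stochastic truth whose rates equal the published cohort's empirical
    positivity proportions and band composition."""
    prob: dict[tuple[str, str], float] = {}
    bands: dict[tuple[str, str], tuple[float, float, float]] = {}
    # aggregate the quota groups per histotype
    agg: dict[str, dict[str, float]] = {}
    for g in STUDY_QUOTA:
        a = agg.setdefault(g.histotype, {"n": 0, "aldh1": 0, "cd34": 0,
                                         "low": 0, "inter": 0, "high": 0})
        a["n"] += g.n
        a["aldh1"] += g.n_pp + g.n_pn
        a["cd34"] += g.n_pp + g.n_np
        lo, it, hi = g.aldh1_bands or (0, 0, 0)
        a["low"] += lo; a["inter"] += it; a["high"] += hi
    for hist, a in agg.items():
        prob[(hist, "ALDH1")] = a["aldh1"] / a["n"]
        prob[(hist, "CD34")] = a["cd34"] / a["n"]
        tot = max(a["low"] + a["inter"] + a["high"], 1)
        bands[(hist, "ALDH1")] = (a["low"] / tot, a["inter"] / tot, a["high"] / tot)
        bands[(hist, "CD34")] = (0.25, 0.5, 0.25)
    return IhcTruth(
        per_histotype_positive_prob=prob,
        band_distribution=bands,
        n_per_histotype={h: int(a["n"]) for h, a in agg.items()},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixtures(
    out_dir: str | Path,
    truth: ExpressionTruth | None = None,
    layouts: list[SetLayout] | None = None,
    ihc_truth: IhcTruth | None = None,
    quota: tuple[QuotaGroup, ...] | None = STUDY_QUOTA,
) -> dict[str, str]:
    """Write TSV matrices, annotation TSVs, cohort CSV and truth JSON.

    Returns a manifest mapping each written file name to its sha256 hash;
    identical truth + seed always produces identical hashes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if truth is None:
        truth = default_truth()
    layouts = layouts or study_layouts()
    esets, probe_annots = simulate_multiplatform_cohort(truth, layouts)

    manifest: dict[str, str] = {}
    ann_frames = []
    for eset in esets:
        fn = out / f"expression_{eset.set_id}.tsv"
        write_expression_tsv(eset, fn)
        manifest[fn.name] = _sha256(fn)
        ann_frames.append(eset.annotations)
    ann_path = out / "sample_annotations.tsv"
    write_sample_annotations(pd.concat(ann_frames), ann_path)
    manifest[ann_path.name] = _sha256(ann_path)

    probe_path = out / "probe_annotations.tsv"
    write_probe_annotations(probe_annots, probe_path)
    manifest[probe_path.name] = _sha256(probe_path)

    cand_path = out / "housekeeping_candidates.txt"
    cand_path.write_text("\n".join(truth.housekeeping_ids) + "\n")
    manifest[cand_path.name] = _sha256(cand_path)

    cohort = quota_ihc_cohort(quota) if quota is not None else simulate_ihc_cohort(
        ihc_truth or default_ihc_truth(seed=truth.seed)
    )
    cohort_path = out / "ihc_cohort.csv"
    cohort.to_csv(cohort_path, index=False, lineterminator="\n")
    manifest[cohort_path.name] = _sha256(cohort_path)

    truth_path = out / "truth.json"
    payload = asdict(truth)
    payload["layouts"] = [
        {"set_id": l.set_id, "platform": l.platform,
         "n_background_genes": l.n_background_genes,
         "blocks": [asdict(b) for b in l.blocks]}
        for l in layouts
    ]
    truth_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    manifest[truth_path.name] = _sha256(truth_path)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
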
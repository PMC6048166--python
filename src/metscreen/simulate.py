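"""Synthetic screen, expression, genomics and titration data with planted truth.

Every analysis stage in this package can be exercised without external
data: the generators here emit the exact dialects the analysis modules
consume (FASTQ, TSV sample sheets, GMT, titration tables) together with
a ground-truth table sufficient to score any hit caller.

Generative model of the pooled in vivo screen
---------------------------------------------
* The clone library is partitioned into pools (default 20 clones/pool,
  one shared control clone per pool), each injected into a cohort of
  mice (default 10).
* Input composition per pool ~ Dirichlet(alpha) over pool members;
  input replicates are multinomial read draws from it.
* Subcutaneous tumors: composition proportional to
  input x fitness x lognormal mouse-level noise, renormalized; tumor
  cores are multinomial draws from the mouse's composition.
* Metastases are clonally bottlenecked: each lesion samples 1..B clones
  (B = ``met_bottleneck``) without replacement with probability
  proportional to tumor abundance x met seeding weight, then draws its
  composition as a Dirichlet over the seeded clones. Non-drivers carry
  weight 1 and therefore rarely seed lesions; this bottleneck dominance
  is exactly the property the metastasis hit rule exploits.
* Sequencing reads are flank + barcode + flank with uniform per-base
  substitution error, emitted as FASTQ on demand (count tables are
  exact pre-error multinomial draws).

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning; identical seeds give bit
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .barcodes import BarcodeLibrary
from .screen import ScreenCounts, ScreenDesign

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

__all__ = [
    "SimulationConfig",
    "PAPER_SCALE",
    "TINY",
    "make_library",
    "simulate_screen",
    "SimulatedScreen",
    "simulate_expression",
    "simulate_cna_mutations",
    "simulate_bret",
    "simulate_bret_experiment",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the pooled-screen generator.

    Defaults mirror the screened design: ~20 clones per pool including a
    control, 10 mice per pool, 24 nt barcodes, quadruplicate input and
    triplicate tumor-core sequencing. Pools mix equal cell numbers per
    clone, so the input Dirichlet is concentrated (alpha = 20, ~20%
    abundance CV). Metastatic seeding is strongly gated (weight 500x for
    drivers): the parental line is essentially non-metastatic, so
    lesions seeded by passenger clones are rare hitchhiking events,
    while the 5x growth fitness of drivers keeps the subcutaneous
    enrichment threshold discriminative rather than trivially passed.
    """

    seed: int = 0
    n_orfs: int = 218  # includes the control clone
    pool_size: int = 20
    mice_per_pool: int = 10
    dirichlet_alpha: float = 20.0
    n_sq_drivers_per_pool: int = 1
    n_met_drivers_per_pool: int = 2
    sq_fitness: float = 5.0
    met_weight: float = 500.0
    met_bottleneck: int = 3
    mets_per_mouse_mean: float = 2.0
    mouse_noise_sigma: float = 0.5
    reads_per_sample: int = 30_000
    input_replicates: int = 4
    sq_cores_per_mouse: int = 3
    per_base_error_rate: float = 0.01
    barcode_length: int = 24
    min_barcode_distance: int = 5
    flank5: str = "ACGTGATCCA"
    flank3: str = "TGGATCACGT"

    def __post_init__(self) -> None:
        if self.n_orfs < self.pool_size:
            raise ValueError("n_orfs must be at least pool_size")
        for name in ("n_orfs", "pool_size", "mice_per_pool", "reads_per_sample",
                     "input_replicates", "sq_cores_per_mouse", "met_bottleneck"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.per_base_error_rate < 1:
            raise ValueError("per_base_error_rate must lie in [0, 1)")


PAPER_SCALE = SimulationConfig()  # 218 clones, 12 pools of <=20, 10 mice/pool
TINY = SimulationConfig(
    n_orfs=30,
    pool_size=10,
    mice_per_pool=3,
    reads_per_sample=2_000,
    input_replicates=2,
    sq_cores_per_mouse=2,
)


def make_library(
    n_orfs: int,
    barcode_length: int = 24,
    min_distance: int = 5,
    seed: int | np.random.Generator = 0,
    max_attempts_per_barcode: int = 10_000,
) -> BarcodeLibrary:
    """Random barcode library with a guaranteed minimum pairwise Hamming distance.

    Rejection sampling: candidates closer than ``min_distance`` to an
    accepted barcode are discarded. Deterministic under a fixed seed.
    """
    if min_distance > barcode_length:
        raise ValueError("min_distance cannot exceed barcode_length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    accepted = np.empty((0, barcode_length), dtype=np.uint8)
    barcodes: list[str] = []
    attempts = 0
    while len(barcodes) < n_orfs:
        cand = rng.choice(BASES, size=barcode_length)
        if accepted.shape[0] == 0 or (accepted != cand).sum(axis=1).min() >= min_distance:
            accepted = np.vstack([accepted, cand])
            barcodes.append(cand.tobytes().decode("ascii"))
            attempts = 0
        else:
            attempts += 1
            if attempts > max_attempts_per_barcode:
                raise RuntimeError(
                    f"could not place barcode {len(barcodes) + 1} of {n_orfs} at "
                    f"length {barcode_length}, distance {min_distance}"
                )
    orf_ids = [f"ORF{i:03d}" for i in range(1, n_orfs)] + ["CTRL"]
    return BarcodeLibrary(orf_ids=orf_ids, barcodes=barcodes, length=barcode_length)


@dataclass
class SimulatedScreen:
    """A simulated screen: design, library, counts, truth, and FASTQ emission."""

    config: SimulationConfig
    library: BarcodeLibrary
    design: ScreenDesign
    counts: ScreenCounts
    truth_orfs: pd.DataFrame  # orf_id, pool_id, is_sq_driver, is_met_driver, ...
    true_abundance: pd.DataFrame  # sample_id x orf_id intended composition
    _fastq_seed: np.random.SeedSequence = field(repr=False, default=None)

    def met_driver_set(self) -> set[str]:
        return set(self.truth_orfs.loc[self.truth_orfs["is_met_driver"], "orf_id"])

    def sq_driver_set(self) -> set[str]:
        return set(self.truth_orfs.loc[self.truth_orfs["is_sq_driver"], "orf_id"])

    def sample_reads(self, sample_id: str) -> list[str]:
        """Sequencing reads (flank + barcode + flank, with substitution
        errors) for one sample, regenerated deterministically."""
        cfg = self.config
        counts = self.counts.counts.loc[sample_id]
        child = np.random.SeedSequence(
            entropy=self._fastq_seed.entropy,
            spawn_key=(*self._fastq_seed.spawn_key, _stable_index(self.counts.counts.index,
                                                                  sample_id)),
        )
        rng = np.random.default_rng(child)
        bc_by_orf = dict(zip(self.library.orf_ids, self.library.barcodes))
        seqs = []
        for orf, k in counts.items():
            seqs.extend([cfg.flank5 + bc_by_orf[orf] + cfg.flank3] * int(k))
        if not seqs:
            return []
        arr = np.vstack([np.frombuffer(s.encode("ascii"), np.uint8) for s in seqs])
        if cfg.per_base_error_rate > 0:
            mask = rng.random(arr.shape) < cfg.per_base_error_rate
            # substitute with one of the three *other* bases
            shift = rng.integers(1, 4, size=arr.shape)
            idx = np.searchsorted(BASES, arr)  # ACGT are sorted bytes
            arr = np.where(mask, BASES[(idx + shift) % 4], arr)
        reads = ["".join(map(chr, row)) for row in arr]
        order = rng.permutation(len(reads))
        return [reads[i] for i in order]

    def write_fastq(self, directory: str | Path, samples: list[str] | None = None) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for sample in samples or self.counts.counts.index:
            path = directory / f"{sample}.fastq"
            with open(path, "w") as handle:
                for i, seq in enumerate(self.sample_reads(sample)):
                    handle.write(f"@{sample}:{i}\n{seq}\n+\n{'I' * len(seq)}\n")
            written.append(path)
        return written


def _stable_index(index: pd.Index, key: str) -> int:
    return int(np.nonzero(index == key)[0][0])


def simulate_screen(config: SimulationConfig = PAPER_SCALE) -> SimulatedScreen:
    """Simulate a pooled in vivo screen under ``config`` (see module docstring)."""
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    lib_seed, abund_seed, fastq_seed = root.spawn(3)
    library = make_library(
        cfg.n_orfs, cfg.barcode_length, cfg.min_barcode_distance,
        np.random.default_rng(lib_seed),
    )
    rng = np.random.default_rng(abund_seed)

    control = "CTRL"
    orfs = [o for o in library.orf_ids if o != control]
    per_pool = cfg.pool_size - 1  # control joins every pool
    pool_ids = [f"pool{p + 1:02d}" for p in range((len(orfs) + per_pool - 1) // per_pool)]
    pools: dict[str, set[str]] = {}
    for p, pool in enumerate(pool_ids):
        members = orfs[p * per_pool : (p + 1) * per_pool]
        pools[pool] = set(members) | {control}

    # plant drivers: disjoint SQ and metastasis drivers per pool (control excluded)
    truth_rows = []
    fitness: dict[str, float] = {o: 1.0 for o in library.orf_ids}
    met_w: dict[str, float] = {o: 1.0 for o in library.orf_ids}
    for pool in pool_ids:
        members = sorted(pools[pool] - {control})
        k = min(len(members), cfg.n_met_drivers_per_pool + cfg.n_sq_drivers_per_pool)
        chosen = list(rng.choice(members, size=k, replace=False))
        met_drivers = chosen[: cfg.n_met_drivers_per_pool]
        sq_drivers = chosen[cfg.n_met_drivers_per_pool :]
        for orf in met_drivers:
            fitness[orf] = cfg.sq_fitness
            met_w[orf] = cfg.met_weight
        for orf in sq_drivers:
            fitness[orf] = cfg.sq_fitness
        for orf in sorted(pools[pool]):
            truth_rows.append(
                {
                    "orf_id": orf,
                    "pool_id": pool,
                    "is_sq_driver": orf in sq_drivers or orf in met_drivers,
                    "is_met_driver": orf in met_drivers,
                    "sq_fitness": fitness[orf],
                    "met_weight": met_w[orf],
                }
            )
    truth = pd.DataFrame(truth_rows)

    sample_rows = []
    count_rows: dict[str, np.ndarray] = {}
    true_rows: dict[str, np.ndarray] = {}
    orf_index = pd.Index(library.orf_ids, name="orf_id")
    orf_pos = {o: i for i, o in enumerate(library.orf_ids)}

    def full_vector(members: list[str], values: np.ndarray) -> np.ndarray:
        vec = np.zeros(len(orf_index))
        for m, v in zip(members, values):
            vec[orf_pos[m]] = v
        return vec

    for pool in pool_ids:
        members = sorted(pools[pool])
        m = len(members)
        input_p = rng.dirichlet(np.full(m, cfg.dirichlet_alpha))
        fit = np.array([fitness[o] for o in members])
        met_weight_vec = np.array([met_w[o] for o in members])

        for r in range(cfg.input_replicates):
            sid = f"{pool}_input_r{r + 1}"
            sample_rows.append(
                {"sample_id": sid, "pool_id": pool, "mouse_id": np.nan,
                 "tissue": "input", "replicate": r + 1}
            )
            count_rows[sid] = full_vector(
                members, rng.multinomial(cfg.reads_per_sample, input_p).astype(float)
            )
            true_rows[sid] = full_vector(members, input_p)

        for mi in range(cfg.mice_per_pool):
            mouse = f"{pool}_m{mi + 1:02d}"
            noise = rng.lognormal(mean=0.0, sigma=cfg.mouse_noise_sigma, size=m)
            w = input_p * fit * noise
            tumor_p = w / w.sum()
            for c in range(cfg.sq_cores_per_mouse):
                sid = f"{mouse}_sq_c{c + 1}"
                sample_rows.append(
                    {"sample_id": sid, "pool_id": pool, "mouse_id": mouse,
                     "tissue": "sq_tumor", "replicate": c + 1}
                )
                count_rows[sid] = full_vector(
                    members, rng.multinomial(cfg.reads_per_sample, tumor_p).astype(float)
                )
                true_rows[sid] = full_vector(members, tumor_p)

            n_mets = rng.poisson(cfg.mets_per_mouse_mean)
            seed_w = tumor_p * met_weight_vec
            seed_p = seed_w / seed_w.sum()
            for lesion in range(n_mets):
                n_seeds = int(rng.integers(1, cfg.met_bottleneck + 1))
                # founding cells drawn with replacement: a dominant clone may
                # contribute several seeds, so lesions hold <= bottleneck clones
                clones = np.unique(rng.choice(m, size=min(n_seeds, m), replace=True, p=seed_p))
                shares = rng.dirichlet(np.ones(clones.size))
                met_p = np.zeros(m)
                met_p[clones] = shares
                sid = f"{mouse}_met_l{lesion + 1}"
                sample_rows.append(
                    {"sample_id": sid, "pool_id": pool, "mouse_id": mouse,
                     "tissue": "lung_met", "replicate": lesion + 1}
                )
                count_rows[sid] = full_vector(
                    members, rng.multinomial(cfg.reads_per_sample, met_p).astype(float)
                )
                true_rows[sid] = full_vector(members, met_p)

    samples = pd.DataFrame(sample_rows)
    mice = {
        str(r["mouse_id"]): str(r["pool_id"])
        for _, r in samples.iterrows()
        if r["tissue"] != "input"
    }
    design = ScreenDesign(pools=pools, mice=mice, samples=samples)
    counts_df = pd.DataFrame(count_rows, index=orf_index).T.astype(int)
    counts_df.index.name = "sample_id"
    qc = pd.DataFrame(
        {
            "assigned": counts_df.sum(axis=1),
            "unassigned": 0,
            "ambiguous": 0,
            "total": counts_df.sum(axis=1),
        }
    )
    true_df = pd.DataFrame(true_rows, index=orf_index).T
    true_df.index.name = "sample_id"
    return SimulatedScreen(
        config=cfg,
        library=library,
        design=design,
        counts=ScreenCounts(counts=counts_df, qc=qc),
        truth_orfs=truth,
        true_abundance=true_df,
        _fastq_seed=fastq_seed,
    )


def simulate_expression(
    n_genes: int = 2_000,
    n_per_group: int = 3,
    planted_log2_fold: float = 1.0,
    n_planted: int = 0,
    noise_sd_log2: float = 0.25,
    baseline_log2_mean: float = 7.0,
    baseline_log2_sd: float = 2.0,
    paired: bool = False,
    pair_sd_log2: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame | list[tuple[str, str]], pd.DataFrame]:
    """Lognormal expression matrix with planted differential genes.

    Returns ``(matrix, design, truth)`` where the matrix is linear-scale
    genes x samples, ``design`` is a pair list (paired) or a sample ->
    group frame (unpaired), and ``truth`` records the planted log2 fold
    change per gene. The first ``n_planted`` genes are up-regulated in
    group2 by ``planted_log2_fold`` on the log2 scale.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes = [f"G{i:05d}" for i in range(n_genes)]
    base = rng.normal(baseline_log2_mean, baseline_log2_sd, size=n_genes)
    effect = np.zeros(n_genes)
    effect[:n_planted] = planted_log2_fold

    g1 = [f"s{i}_g1" for i in range(n_per_group)]
    g2 = [f"s{i}_g2" for i in range(n_per_group)]
    if paired:
        pair_shift = rng.normal(0.0, pair_sd_log2, size=(n_genes, n_per_group))
        log1 = base[:, None] + pair_shift + rng.normal(0, noise_sd_log2, (n_genes, n_per_group))
        log2_ = (
            base[:, None]
            + pair_shift
            + effect[:, None]
            + rng.normal(0, noise_sd_log2, (n_genes, n_per_group))
        )
        design: pd.DataFrame | list[tuple[str, str]] = list(zip(g1, g2))
    else:
        log1 = base[:, None] + rng.normal(0, noise_sd_log2, (n_genes, n_per_group))
        log2_ = base[:, None] + effect[:, None] + rng.normal(0, noise_sd_log2, (n_genes, n_per_group))
        design = pd.DataFrame(
            {"sample_id": g1 + g2, "group": ["g1"] * n_per_group + ["g2"] * n_per_group}
        )
    mat = pd.DataFrame(
        np.hstack([2.0**log1, 2.0**log2_]), index=pd.Index(genes, name="gene_id"),
        columns=g1 + g2,
    )
    truth = pd.DataFrame(
        {"gene_id": genes, "planted_log2_fold": effect, "is_planted": effect != 0.0}
    )
    return mat, design, truth


def simulate_cna_mutations(
    n_genes: int = 500,
    n_samples: int = 154,
    n_amp_genes: int = 20,
    amp_fraction: float = 0.05,
    amp_ratio_range: tuple[float, float] = (1.5, 4.0),
    n_mut_genes: int = 10,
    background_sigma: float = 0.08,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Copy-ratio matrix and mutation records with planted recurrent events.

    The first ``n_amp_genes`` genes are amplified (ratio drawn from
    ``amp_ratio_range``) in ``ceil(amp_fraction * n_samples)`` samples,
    guaranteeing they meet an inclusive >= recurrence threshold at
    exactly that fraction. The first ``n_mut_genes`` genes additionally
    receive one validated missense record each; unvalidated and
    non-missense decoy records are scattered over other genes.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"T{i:03d}" for i in range(n_samples)]
    ratios = rng.lognormal(mean=0.0, sigma=background_sigma, size=(n_genes, n_samples))
    ratios = np.minimum(ratios, 1.45)  # background never crosses the amplification cut
    n_amp_samples = int(np.ceil(amp_fraction * n_samples))
    for g in range(n_amp_genes):
        cols = rng.choice(n_samples, size=n_amp_samples, replace=False)
        ratios[g, cols] = rng.uniform(*amp_ratio_range, size=n_amp_samples)
    cna = pd.DataFrame(ratios, index=pd.Index(genes, name="gene_id"), columns=samples)

    mut_rows = []
    for g in range(n_mut_genes):
        mut_rows.append(
            {
                "gene_id": genes[g],
                "sample_id": samples[int(rng.integers(n_samples))],
                "variant_class": "missense",
                "validated": True,
            }
        )
    decoy_classes = ["nonsense", "silent", "frameshift", "missense"]
    for _ in range(n_mut_genes * 2):
        mut_rows.append(
            {
                "gene_id": genes[int(rng.integers(n_mut_genes, n_genes))],
                "sample_id": samples[int(rng.integers(n_samples))],
                "variant_class": decoy_classes[int(rng.integers(len(decoy_classes)))],
                "validated": bool(rng.integers(2)),
            }
        )
    # decoy missense records on non-planted genes are left unvalidated
    muts = pd.DataFrame(mut_rows)
    decoy = muts.index >= n_mut_genes
    muts.loc[decoy & (muts["variant_class"] == "missense"), "validated"] = False
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "is_amplified": [g < n_amp_genes for g in range(n_genes)],
            "is_validated_missense": [g < n_mut_genes for g in range(n_genes)],
        }
    )
    return cna, muts, truth


def simulate_bret(
    bret_max: float,
    k_half: float,
    x_grid: np.ndarray | list[float],
    noise_sd: float = 0.02,
    n_reps: int = 3,
    seed: int = 0,
    donor_baseline: float = 0.35,
    l460: float = 1_000.0,
    condition: str = "pair",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Titration table for one condition on a one-site binding curve.

    Each replicate yields one row per ``x_grid`` point with consistent
    channel values: L460 fixed, venus_FI = x * L460, and I535 such that
    the bleed-through corrected net BRET equals
    ``bret_max * x / (k_half + x) * (1 + eps)`` with multiplicative
    Gaussian noise ``eps ~ N(0, noise_sd)``. Donor-only control rows
    (x = 0, ratio = ``donor_baseline``) are included per replicate.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    x = np.asarray(x_grid, dtype=float)
    rows = []
    for rep in range(1, n_reps + 1):
        rows.append(
            {
                "condition": "donor_only",
                "replicate": rep,
                "L460": l460,
                "I535": donor_baseline * l460,
                "venus_FI": 0.0,
            }
        )
        y_true = bret_max * x / (k_half + x)
        y = y_true * (1.0 + rng.normal(0.0, noise_sd, size=x.size)) if noise_sd > 0 else y_true
        for xi, yi in zip(x, y):
            rows.append(
                {
                    "condition": condition,
                    "replicate": rep,
                    "L460": l460,
                    "I535": (donor_baseline + yi) * l460,
                    "venus_FI": xi * l460,
                }
            )
    truth = {"bret_max": float(bret_max), "k_half": float(k_half)}
    return pd.DataFrame(rows), truth


def simulate_bret_experiment(
    bret_max_pair: float = 0.25,
    bret_max_control: float = 0.05,
    k_half: float = 0.5,
    x_grid: np.ndarray | list[float] | None = None,
    noise_sd: float = 0.02,
    n_reps: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Pair + acceptor-control titrations sharing one x grid and plate layout."""
    if x_grid is None:
        x_grid = np.linspace(0.1, 5.0, 8)
    ss = np.random.SeedSequence(seed)
    s_pair, s_ctrl = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    pair, truth_pair = simulate_bret(
        bret_max_pair, k_half, x_grid, noise_sd, n_reps, s_pair, condition="pair"
    )
    ctrl, truth_ctrl = simulate_bret(
        bret_max_control, k_half, x_grid, noise_sd, n_reps, s_ctrl,
        condition="acceptor_control",
    )
    ctrl = ctrl[ctrl["condition"] != "donor_only"]
    plate = pd.concat([pair, ctrl], ignore_index=True)
    truth = {
        "bret_max_pair": truth_pair["bret_max"],
        "bret_max_control": truth_ctrl["bret_max"],
        "k_half": k_half,
    }
    return plate, truth
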
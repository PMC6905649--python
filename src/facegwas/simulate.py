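"""Synthetic cohort generator.

Produces phased genotype panels and 3D facial landmark configurations with
the statistical structure the downstream pipeline assumes: founder-mosaic
haplotypes with a controllable allele-frequency spectrum, additive SNP
effects on inter-landmark distances, sex and age effects, an ACE
(additive / common-environment / unique) decomposition of landmark noise
for twin pairs, multiple populations with divergent allele frequencies, and
optional partial sweeps that create long shared haplotypes around a core
variant.

Effect sizes are specified as fractions of the baseline phenotypic variance
of a distance (2 * noise_sd**2, the variance induced by i.i.d. landmark
placement noise at its two endpoints), so that simulated regression
coefficients are recoverable on the phenotype scale.  Each individual's
configuration is finally corrupted by a random similarity transform
(rotation, translation, global scale) that Procrustes alignment must
remove.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypePanel, LandmarkSet
from .registry import LANDMARK_NAMES, distance_endpoints, distance_name

#: Bilaterally symmetric 13-landmark template face, in mm.  x is lateral
#: (right negative), y vertical, z forward protrusion.
TEMPLATE_FACE = np.array(
    [
        [-44.0, 30.0, 0.0],   # ExR
        [44.0, 30.0, 0.0],    # ExL
        [-16.0, 28.0, 6.0],   # EnR
        [16.0, 28.0, 6.0],    # EnL
        [0.0, 32.0, 10.0],    # Nsn
        [0.0, -2.0, 32.0],    # Prn
        [0.0, -12.0, 20.0],   # Sbn
        [-16.0, -6.0, 14.0],  # AlR
        [16.0, -6.0, 14.0],   # AlL
        [0.0, -22.0, 18.0],   # Ls
        [0.0, -38.0, 14.0],   # Li
        [-24.0, -30.0, 8.0],  # ChR
        [24.0, -30.0, 8.0],   # ChL
    ]
)

_LM_INDEX = {name: i for i, name in enumerate(LANDMARK_NAMES)}


@dataclass
class PopulationSpec:
    """One simulated population: sample count and allele-frequency shift.

    ``af_shift`` is added (with a per-variant random sign) to the base
    founder allele frequency, producing genome-wide divergence between
    populations.
    """

    label: str
    n_samples: int
    af_shift: float = 0.0


@dataclass
class SweepSpec:
    """Partial selective sweep at a core variant.

    A ``carrier_fraction`` of haplotypes in the target population copy the
    favored founder outward from the core for an exponentially distributed
    length (mean ``segment_mean_bp`` per direction; ``inf`` copies the whole
    region), creating extended haplotype homozygosity on the derived
    background.  Carriers receive the derived core allele; non-carriers the
    ancestral one, so the derived allele frequency at the core equals the
    carrier fraction.
    """

    carrier_fraction: float
    core_index: int | None = None       # defaults to the middle variant
    segment_mean_bp: float = 250_000.0
    population: str | None = None       # defaults to the first population


@dataclass
class SimSpec:
    """Full parameterization of a synthetic cohort.

    Defaults give a single 600-sample population typed at 1,000 variants in
    a 1 Mb region, landmark placement noise of 1 mm per coordinate (hence a
    baseline distance variance of 2 mm^2), sex and age effects jointly
    explaining up to ~21% of the variance of the most affected distances,
    and per-SNP causal effects capped at 5% of variance each.
    """

    n_samples: int = 600
    n_variants: int = 1000
    n_founder_haplotypes: int = 40
    region_length_bp: int = 1_000_000
    switch_rate: float = 1e-6           # mosaic switches per bp
    maf_bounds: tuple[float, float] = (0.05, 0.5)
    causal: dict[str, tuple[str, float]] = field(default_factory=dict)
    sex_effects: dict[str, float] = field(
        default_factory=lambda: {
            "AlR-Ls": 0.95, "AlL-Ls": 0.95, "AlR-AlL": 0.71, "ExR-ExL": 0.57,
        }
    )
    age_range: tuple[float, float] = (20.0, 70.0)
    age_slopes: dict[str, float] = field(
        default_factory=lambda: {
            "AlR-Ls": 0.022, "AlL-Ls": 0.022, "Ls-Li": -0.015, "ChR-ChL": 0.013,
        }
    )
    n_mz_pairs: int = 0
    n_dz_pairs: int = 0
    twin_h2: float = 0.0                # latent additive fraction of noise variance
    twin_c2: float = 0.0                # shared-environment fraction
    populations: list[PopulationSpec] | None = None
    sweep: SweepSpec | None = None
    noise_sd: float = 1.0               # per-coordinate landmark noise, mm
    apply_nuisance: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_bounds
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"infeasible maf bounds {self.maf_bounds}")
        for vid, (dist, vf) in self.causal.items():
            distance_endpoints(dist)  # validates the name
            # sign encodes the effect direction; magnitude is the variance fraction
            if not abs(vf) <= 0.05:
                raise ValueError(f"causal variance fraction {vf} for {vid} outside [-0.05, 0.05]")
        if self.twin_h2 + self.twin_c2 > 1.0:
            raise ValueError("twin_h2 + twin_c2 must not exceed 1")
        if self.sweep is not None and not (0.0 <= self.sweep.carrier_fraction <= 1.0):
            raise ValueError("carrier fraction must be in [0, 1]")
        if self.populations is None:
            self.populations = [PopulationSpec("POP1", self.n_samples)]

    @property
    def baseline_variance(self) -> float:
        """Baseline variance of a distance phenotype (2 * noise_sd**2)."""
        return 2.0 * self.noise_sd**2


# ---------------------------------------------------------------------------
# haplotypes
# ---------------------------------------------------------------------------

def _founder_pool(rng, spec: SimSpec, n_pops: int):
    """Per-population founder haplotype pools with shifted frequencies."""
    lo, hi = spec.maf_bounds
    nf = spec.n_founder_haplotypes
    if not any(lo <= k / nf <= hi for k in range(nf + 1)):
        raise ValueError(
            f"maf bounds {spec.maf_bounds} infeasible with {nf} founder haplotypes"
        )
    base_q = rng.uniform(lo, hi, size=spec.n_variants)
    signs = rng.choice([-1.0, 1.0], size=spec.n_variants)
    pools = []
    for p, pop in enumerate(spec.populations):
        q = np.clip(base_q + signs * pop.af_shift, 0.01, 0.99)
        pool = (rng.random((nf, spec.n_variants)) < q).astype(np.int8)
        if pop.af_shift == 0.0:
            # enforce the spectrum on the unshifted pool by redrawing columns
            for _ in range(200):
                freq = pool.mean(axis=0)
                bad = np.flatnonzero((freq < lo) | (freq > hi))
                if bad.size == 0:
                    break
                pool[:, bad] = (rng.random((nf, bad.size)) < base_q[bad]).astype(np.int8)
            else:
                raise ValueError(f"could not realize maf bounds {spec.maf_bounds}")
        pools.append(pool)
    return pools


def _mosaic_haplotype(rng, pool: np.ndarray, positions: np.ndarray, switch_rate: float):
    """One haplotype as a founder mosaic with exponential segment lengths.

    Switch points form a Poisson process of the given per-bp rate over the
    region; each segment copies a uniformly chosen founder.
    """
    nf = pool.shape[0]
    if switch_rate <= 0:
        cur = rng.integers(nf)
        founder = np.full(len(positions), cur, dtype=np.int32)
        return pool[cur].copy(), founder
    span = float(positions[-1] - positions[0])
    n_switch = rng.poisson(switch_rate * span)
    cuts = np.sort(rng.uniform(positions[0], positions[-1], size=n_switch))
    founders = rng.integers(nf, size=n_switch + 1).astype(np.int32)
    founder = founders[np.searchsorted(cuts, positions, side="right")]
    return pool[founder, np.arange(len(positions))], founder


def simulate_haplotypes(spec: SimSpec) -> tuple[GenotypePanel, pd.DataFrame]:
    """Simulate a phased genotype panel of founder-mosaic haplotypes.

    Returns the panel plus a sample table with columns ``sample,
    population, zygosity, twin_pair``.  Twin pairs (appended to the first
    population) share haplotypes: monozygotic co-twins are exact copies;
    dizygotic co-twins re-draw each of the two haplotypes with probability
    1/2, sharing half on average.
    """
    if spec.n_founder_haplotypes < 2:
        raise ValueError("need at least 2 founder haplotypes")
    rng = np.random.default_rng(spec.seed)
    positions = np.sort(
        rng.choice(np.arange(1, spec.region_length_bp + 1), size=spec.n_variants, replace=False)
    )
    pools = _founder_pool(rng, spec, len(spec.populations))

    haps: list[np.ndarray] = []
    sample_rows: list[dict] = []
    hap_pop: list[int] = []

    def add_sample(name, pop_i, zygosity="NA", pair="NA", hap_pair=None):
        if hap_pair is None:
            hap_pair = [
                _mosaic_haplotype(rng, pools[pop_i], positions, spec.switch_rate)[0]
                for _ in range(2)
            ]
        haps.extend(hap_pair)
        hap_pop.extend([pop_i, pop_i])
        sample_rows.append(
            {
                "sample": name,
                "population": spec.populations[pop_i].label,
                "zygosity": zygosity,
                "twin_pair": pair,
            }
        )

    for pop_i, pop in enumerate(spec.populations):
        for s in range(pop.n_samples):
            add_sample(f"{pop.label}_S{s:05d}", pop_i)

    # twin pairs in the first population
    pair_id = 0
    for zyg, n_pairs in (("MZ", spec.n_mz_pairs), ("DZ", spec.n_dz_pairs)):
        for _ in range(n_pairs):
            pair_id += 1
            pair = f"PAIR{pair_id:04d}"
            lbl = spec.populations[0].label
            h1 = [_mosaic_haplotype(rng, pools[0], positions, spec.switch_rate)[0] for _ in range(2)]
            if zyg == "MZ":
                h2 = [h.copy() for h in h1]
            else:
                h2 = [
                    h1[j].copy()
                    if rng.random() < 0.5
                    else _mosaic_haplotype(rng, pools[0], positions, spec.switch_rate)[0]
                    for j in range(2)
                ]
            add_sample(f"{lbl}_T{pair_id:04d}A", 0, zyg, pair, h1)
            add_sample(f"{lbl}_T{pair_id:04d}B", 0, zyg, pair, h2)

    H = np.array(haps, dtype=np.int8)
    hap_pop = np.array(hap_pop)

    if spec.sweep is not None:
        _apply_sweep(rng, H, hap_pop, positions, pools, spec)

    dosages = (H[0::2] + H[1::2]).astype(float)
    sample_table = pd.DataFrame(sample_rows)
    variants = pd.DataFrame(
        {
            "id": [f"var{j:05d}" for j in range(spec.n_variants)],
            "chrom": "1",
            "pos": positions,
            "ea": "A",  # derived / effect allele
            "oa": "G",
            "aa": "G",  # ancestral allele = reference
        }
    )
    panel = GenotypePanel(dosages, variants, list(sample_table["sample"]), H)
    return panel, sample_table


def _apply_sweep(rng, H, hap_pop, positions, pools, spec: SimSpec) -> None:
    sw = spec.sweep
    core = sw.core_index if sw.core_index is not None else spec.n_variants // 2
    pop_labels = [p.label for p in spec.populations]
    pop_i = pop_labels.index(sw.population) if sw.population else 0
    pool = pools[pop_i]
    carriers_possible = np.flatnonzero(hap_pop == pop_i)
    # favored founder: any founder carrying the derived allele at the core
    derived = np.flatnonzero(pool[:, core] == 1)
    fav = derived[0] if derived.size else 0
    pool[fav, core] = 1
    core_pos = positions[core]
    n_car = int(round(sw.carrier_fraction * carriers_possible.size))
    car = rng.choice(carriers_possible, size=n_car, replace=False)
    is_car = np.zeros(H.shape[0], dtype=bool)
    is_car[car] = True
    for h in carriers_possible:
        if is_car[h]:
            if math.isinf(sw.segment_mean_bp):
                left, right = -np.inf, np.inf
            else:
                left = core_pos - rng.exponential(sw.segment_mean_bp)
                right = core_pos + rng.exponential(sw.segment_mean_bp)
            seg = (positions >= left) & (positions <= right)
            H[h, seg] = pool[fav, seg]
            H[h, core] = 1
        else:
            H[h, core] = 0


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def _random_rotation(rng) -> np.ndarray:
    """Uniform random 3D rotation (proper, det = +1) via QR of a Gaussian."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def causal_effect_sizes(spec: SimSpec, panel: GenotypePanel) -> pd.DataFrame:
    """True per-dosage effect sizes implied by the causal map.

    beta = sqrt(vf * V0 / (2 p (1 - p))) with V0 the baseline distance
    variance and p the realized effect-allele frequency, so the variant
    explains the requested fraction vf of baseline phenotypic variance.
    """
    vid_idx = {v: j for j, v in enumerate(panel.variants["id"])}
    freq = panel.allele_freq()
    rows = []
    for vid, (dist, vf) in spec.causal.items():
        if vid not in vid_idx:
            raise KeyError(f"causal map references unknown variant {vid!r}")
        j = vid_idx[vid]
        p = freq[j]
        het = 2.0 * p * (1.0 - p)
        beta = 0.0
        if vf != 0 and het > 0:
            beta = math.copysign(
                math.sqrt(abs(vf) * spec.baseline_variance / het), vf
            )
        rows.append({"variant": vid, "index": j, "distance": dist, "vf": vf, "beta": beta})
    return pd.DataFrame(rows, columns=["variant", "index", "distance", "vf", "beta"])


def simulate_landmarks(
    panel: GenotypePanel, sample_table: pd.DataFrame, spec: SimSpec
) -> tuple[LandmarkSet, pd.DataFrame, pd.DataFrame]:
    """Simulate landmark configurations for every sample in *panel*.

    Causal dosages shift the two endpoint landmarks of the target distance
    symmetrically along their connecting axis (so the distance changes by
    beta per dosage unit); sex and age effects are applied the same way.
    Landmark noise is decomposed into additive-genetic, common-environment
    and unique parts according to ``twin_h2``/``twin_c2`` (monozygotic
    co-twins share the additive part, dizygotic co-twins correlate 0.5).
    Finally each configuration is hit by a random rotation, translation and
    global scale unless ``apply_nuisance`` is off.

    Returns (landmarks, covariates, truth) where truth holds the realized
    per-variant effect sizes on the phenotype scale.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n = panel.n_samples
    truth = causal_effect_sizes(spec, panel)

    zyg = sample_table["zygosity"].to_numpy()
    pair = sample_table["twin_pair"].to_numpy()

    # sex and age, shared within twin pairs (same-sex pairs)
    sex = rng.integers(0, 2, size=n).astype(float)
    age = rng.uniform(*spec.age_range, size=n)
    first_of_pair: dict[str, int] = {}
    for i in range(n):
        if pair[i] != "NA":
            if pair[i] in first_of_pair:
                j = first_of_pair[pair[i]]
                sex[i] = sex[j]
                age[i] = age[j]
            else:
                first_of_pair[pair[i]] = i

    # ACE landmark noise
    sd_a = spec.noise_sd * math.sqrt(spec.twin_h2)
    sd_c = spec.noise_sd * math.sqrt(spec.twin_c2)
    sd_e = spec.noise_sd * math.sqrt(max(0.0, 1.0 - spec.twin_h2 - spec.twin_c2))
    A = rng.standard_normal((n, 13, 3)) * sd_a
    C = rng.standard_normal((n, 13, 3)) * sd_c
    E = rng.standard_normal((n, 13, 3)) * sd_e
    for pr, i0 in first_of_pair.items():
        members = np.flatnonzero(pair == pr)
        i1 = [m for m in members if m != i0][0]
        C[i1] = C[i0]
        if zyg[i0] == "MZ":
            A[i1] = A[i0]
        else:  # DZ: additive values correlate 0.5
            A[i1] = 0.5 * A[i0] + math.sqrt(0.75) * A[i1]

    coords = np.repeat(TEMPLATE_FACE[None, :, :], n, axis=0)

    def displace(dist: str, amounts: np.ndarray) -> None:
        a, b = distance_endpoints(dist)
        ia, ib = _LM_INDEX[a], _LM_INDEX[b]
        u = TEMPLATE_FACE[ib] - TEMPLATE_FACE[ia]
        u = u / np.linalg.norm(u)
        coords[:, ia, :] -= 0.5 * amounts[:, None] * u
        coords[:, ib, :] += 0.5 * amounts[:, None] * u

    for _, row in truth.iterrows():
        dos = np.nan_to_num(panel.dosages[:, int(row["index"])])
        displace(row["distance"], row["beta"] * dos)
    for dist, shift in spec.sex_effects.items():
        displace(dist, shift * sex)
    mid_age = 0.5 * (spec.age_range[0] + spec.age_range[1])
    for dist, slope in spec.age_slopes.items():
        displace(dist, slope * (age - mid_age))

    coords += A + C + E

    if spec.apply_nuisance:
        scales = np.exp(rng.uniform(math.log(0.8), math.log(1.25), size=n))
        for i in range(n):
            R = _random_rotation(rng)
            t = rng.uniform(-20.0, 20.0, size=3)
            coords[i] = scales[i] * coords[i] @ R.T + t

    lms = LandmarkSet(coords, list(panel.samples))
    covars = pd.DataFrame(
        {
            "sample": panel.samples,
            "sex": sex.astype(int),
            "age": age,
            "population": sample_table["population"].to_numpy(),
            "zygosity": zyg,
            "twin_pair": pair,
        }
    )
    return lms, covars, truth


def simulate_cohort(spec: SimSpec):
    """Convenience wrapper: haplotypes + landmarks + covariates + truth."""
    panel, sample_table = simulate_haplotypes(spec)
    lms, covars, truth = simulate_landmarks(panel, sample_table, spec)
    return panel, lms, covars, truth
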
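"""Synthetic generators emulating the selection and measurement processes.

The real study's sequencing libraries and time-constant table are not
publicly deposited, so every downstream stage of this package is exercised
on synthetic data with the same statistical structure:

* a ground-truth :class:`AffinityModel` scoring 30-nt inserts by base
  composition, dimer composition and position-anchored motifs (the motif
  term makes affinity order-dependent, mirroring the scramble experiments);
* SELEX-style rounds as Boltzmann-weighted multinomial resampling plus
  lognormal PCR amplification noise;
* first-order exponential blue-shift kinetic traces with optional censoring
  (no measurable shift = very strong binding);
* geometric toy trajectories with planted near-surface / far-from-surface
  hydrogen-bonded base pairs around a 0.6-nm-radius cylinder.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .sequences import ALPHABET, INSERT_LENGTH, SequenceRecord, require_insert
from .trajectory import CNT_RADIUS_NM, Trajectory


class GeneratorError(ValueError):
    pass


# ---------------------------------------------------------------------------
# ground-truth affinity model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AffinityModel:
    """Additive ground-truth score for a 30-nt insert.

    score(s) = sum_i base_weights[s_i]
             + sum_i dimer_weights[s_i s_{i+1}]
             + sum over (pos, motif, w): w if s[pos:pos+3] == motif

    ``temperature`` controls selection softness (Boltzmann factor
    exp(score/temperature) in the round simulator).
    """

    base_weights: dict = field(default_factory=dict)
    dimer_weights: dict = field(default_factory=dict)
    motif_weights: tuple = ()  # tuples (position, 3-mer, weight)
    temperature: float = 1.0

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise GeneratorError("temperature must be > 0")
        for w in list(self.base_weights.values()) + list(self.dimer_weights.values()):
            if not np.isfinite(w):
                raise GeneratorError("weights must be finite")
        for pos, motif, w in self.motif_weights:
            if not (0 <= pos <= INSERT_LENGTH - 3):
                raise GeneratorError(f"motif position {pos} outside [0, 27]")
            if len(motif) != 3 or set(motif) - set(ALPHABET):
                raise GeneratorError(f"motif must be a 3-mer over ACGT: {motif!r}")
            if not np.isfinite(w):
                raise GeneratorError("motif weights must be finite")


def score_sequence(model: AffinityModel, seq: str) -> float:
    """Ground-truth affinity score of a valid 30-nt insert."""
    require_insert(seq)
    score = sum(model.base_weights.get(b, 0.0) for b in seq)
    score += sum(
        model.dimer_weights.get(seq[i : i + 2], 0.0) for i in range(len(seq) - 1)
    )
    score += sum(
        w for pos, motif, w in model.motif_weights if seq[pos : pos + 3] == motif
    )
    return float(score)


def ac_favoring_model(
    strength: float = 0.1, temperature: float = 1.0
) -> AffinityModel:
    """Convenience model favouring A/C and penalising G/T, the qualitative
    pattern the selection experiment enriches for."""
    return AffinityModel(
        base_weights={"A": strength, "C": strength, "G": -strength, "T": -strength},
        temperature=temperature,
    )


# ---------------------------------------------------------------------------
# library / selection rounds
# ---------------------------------------------------------------------------


@dataclass
class LibraryRound:
    round_index: int
    records: list[SequenceRecord]
    seed: int

    def total_count(self) -> int:
        return sum(r.count for r in self.records)


def _random_inserts(rng: np.random.Generator, n: int) -> list[str]:
    arr = rng.integers(0, 4, size=(n, INSERT_LENGTH))
    lut = np.array(list(ALPHABET))
    return ["".join(row) for row in lut[arr]]


def generate_initial_library(
    n_unique: int, counts_dist: str = "uniform", seed: int = 0
) -> LibraryRound:
    """Round-0 library: i.i.d. uniform random 30-nt inserts.

    counts_dist 'uniform' gives every sequence count 1; 'geometric' draws
    counts from a geometric distribution (mean ~3) to emulate uneven
    template abundance.
    """
    if n_unique < 1:
        raise GeneratorError("n_unique must be >= 1")
    if counts_dist not in ("uniform", "geometric"):
        raise GeneratorError(f"unknown counts_dist {counts_dist!r}")
    rng = np.random.default_rng(seed)
    seqs = _random_inserts(rng, n_unique)
    if counts_dist == "uniform":
        counts = np.ones(n_unique, dtype=int)
    else:
        counts = rng.geometric(1.0 / 3.0, size=n_unique)
    # aggregate the (vanishingly unlikely at desk scale) duplicate draws
    agg: dict[str, int] = {}
    for s, c in zip(seqs, counts):
        agg[s] = agg.get(s, 0) + int(c)
    records = [SequenceRecord(s, c) for s, c in agg.items()]
    return LibraryRound(round_index=0, records=records, seed=seed)


def simulate_selection_round(
    prev: LibraryRound,
    model: AffinityModel,
    n_draw: int,
    pcr_cv: float = 0.0,
    seed: int = 0,
) -> LibraryRound:
    """One selection + amplification cycle.

    Sequences are drawn with replacement with probability proportional to
    count * exp(score/temperature) (a Boltzmann selection factor), then each
    surviving sequence's count is multiplied by a mean-1 lognormal factor
    with coefficient of variation *pcr_cv* (PCR amplification noise) and
    rounded.
    """
    if not prev.records:
        raise GeneratorError("previous round is empty")
    if n_draw < 1:
        raise GeneratorError("n_draw must be >= 1")
    if pcr_cv < 0:
        raise GeneratorError("pcr_cv must be >= 0")
    rng = np.random.default_rng(seed)
    counts = np.array([r.count for r in prev.records], dtype=float)
    scores = np.array([score_sequence(model, r.sequence) for r in prev.records])
    logw = scores / model.temperature
    w = counts * np.exp(logw - logw.max())
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise GeneratorError("selection weights sum to zero or overflow")
    drawn = rng.multinomial(n_draw, w / total)
    keep = drawn > 0
    new_counts = drawn[keep].astype(float)
    if pcr_cv > 0:
        sigma = np.sqrt(np.log1p(pcr_cv**2))
        factors = rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=keep.sum())
        new_counts = np.maximum(np.rint(new_counts * factors), 0)
    survivors = new_counts > 0
    records = [
        SequenceRecord(prev.records[i].sequence, int(c))
        for i, c in zip(np.nonzero(keep)[0][survivors], new_counts[survivors])
    ]
    if not records:
        raise GeneratorError("all counts rounded to zero after PCR noise")
    return LibraryRound(round_index=prev.round_index + 1, records=records, seed=seed)


def simulate_selection(
    model: AffinityModel,
    n_unique: int,
    n_rounds: int,
    n_draw: int,
    pcr_cv: float = 0.2,
    seed: int = 0,
) -> list[LibraryRound]:
    """Round 0 plus *n_rounds* selection cycles, seeded per round."""
    rounds = [generate_initial_library(n_unique, seed=seed)]
    for r in range(1, n_rounds + 1):
        rounds.append(
            simulate_selection_round(
                rounds[-1], model, n_draw=n_draw, pcr_cv=pcr_cv, seed=seed + 1000 + r
            )
        )
    return rounds


# ---------------------------------------------------------------------------
# kinetic traces
# ---------------------------------------------------------------------------


@dataclass
class KineticTrace:
    """A fluorescence peak-wavelength time series around surfactant addition."""

    times: np.ndarray  # s, strictly increasing
    wavelengths: np.ndarray  # nm
    t_add: float  # s, surfactant addition time

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if len(self.times) != len(self.wavelengths):
            raise GeneratorError("times and wavelengths must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise GeneratorError("times must be strictly increasing")
        if not (self.times[0] <= self.t_add <= self.times[-1]):
            raise GeneratorError("t_add outside the observation window")

    def to_tsv(self, path: str | Path) -> None:
        import json

        path = Path(path)
        pd.DataFrame({"time_s": self.times, "wavelength_nm": self.wavelengths}).to_csv(
            path, sep="\t", index=False
        )
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps({"t_add_s": self.t_add})
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KineticTrace":
        import json

        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            times=df["time_s"].to_numpy(),
            wavelengths=df["wavelength_nm"].to_numpy(),
            t_add=meta["t_add_s"],
        )


def simulate_kinetic_trace(
    tau_s: float | None,
    lambda0_nm: float = 1129.0,
    lambdaInf_nm: float = 1115.0,
    dt_s: float = 20.0,
    total_s: float = 600.0,
    t_add_s: float = 100.0,
    noise_sd_nm: float = 0.0,
    seed: int = 0,
) -> KineticTrace:
    """First-order displacement trace.

    lambda(t) = lambda0 for t < t_add, then
    lambdaInf + (lambda0 - lambdaInf) * exp(-(t - t_add)/tau) + noise.
    ``tau_s=None`` simulates a censored (no-shift) trace: flat at lambda0.
    Defaults follow the measurement protocol: 20-s sampling over ~10 min
    with surfactant added at 100 s, peak shifting 1129 -> 1115 nm.
    """
    if dt_s <= 0:
        raise GeneratorError("dt_s must be > 0")
    if total_s <= t_add_s:
        raise GeneratorError("total_s must exceed t_add_s")
    if tau_s is not None and not tau_s > 0:
        raise GeneratorError("tau_s must be > 0 (or None for a censored trace)")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, total_s + dt_s / 2, dt_s)
    lam = np.full_like(times, float(lambda0_nm))
    if tau_s is not None:
        after = times >= t_add_s
        lam[after] = lambdaInf_nm + (lambda0_nm - lambdaInf_nm) * np.exp(
            -(times[after] - t_add_s) / tau_s
        )
    if noise_sd_nm > 0:
        lam = lam + rng.normal(0.0, noise_sd_nm, size=times.shape)
    return KineticTrace(times=times, wavelengths=lam, t_add=t_add_s)


# ---------------------------------------------------------------------------
# synthetic affinity table (time constants per sequence)
# ---------------------------------------------------------------------------


def simulate_affinity_table(
    model: AffinityModel,
    sequences: Sequence[str],
    seed: int = 0,
    threshold_s: float = 90.0,
    n_high: int | None = None,
    spread: float = 0.6,
    noise_sd: float = 0.25,
    censor_limit_s: float = 600.0,
) -> pd.DataFrame:
    """Map ground-truth scores to measured-style time constants.

    tau is a lognormal monotone function of a noisy score: sequences the
    model scores higher get longer displacement times; taus beyond the
    observation window (*censor_limit_s*) are censored (no measurable
    shift).  When *n_high* is given, the score->tau mapping is anchored so
    that exactly *n_high* sequences sit at or above *threshold_s* (emulating
    a measured dataset with a stated class composition).
    """
    rng = np.random.default_rng(seed)
    scores = np.array([score_sequence(model, s) for s in sequences], dtype=float)
    sd = scores.std() or 1.0
    raw = scores + rng.normal(0.0, noise_sd * sd, size=len(scores))
    if n_high is not None:
        if not 0 < n_high < len(sequences):
            raise GeneratorError("n_high must be strictly inside (0, n_sequences)")
        order = np.sort(raw)[::-1]
        cut = 0.5 * (order[n_high - 1] + order[n_high])
    else:
        cut = raw.mean()
    raw_sd = raw.std() or 1.0
    tau = threshold_s * np.exp((raw - cut) / (spread * raw_sd))
    censored = tau > censor_limit_s
    tau = np.where(censored, np.nan, tau)
    return pd.DataFrame(
        {
            "sequence": list(sequences),
            "tau_s": tau,
            "censored": censored,
        }
    )


def generate_motif_dataset(
    n: int,
    motifs: Sequence[tuple[int, str]] = ((4, "ACG"), (15, "TTC"), (24, "GCA")),
    seed: int = 0,
) -> tuple[list[str], np.ndarray]:
    """Balanced order-dependent classification task.

    Positives are random inserts with one of the position-anchored 3-mers
    implanted at its anchor; negatives are random inserts carrying none of
    them.  Base composition barely differs between classes, so a classifier
    can only succeed by reading base order — the discriminative signal a
    composition-preserving shuffle destroys.
    """
    if n < 2:
        raise GeneratorError("n must be >= 2")
    rng = np.random.default_rng(seed)
    n_pos = n // 2

    def has_motif(s: str) -> bool:
        return any(s[p : p + 3] == m for p, m in motifs)

    seqs: list[str] = []
    labels: list[int] = []
    while len(seqs) < n_pos:
        s = _random_inserts(rng, 1)[0]
        p, m = motifs[rng.integers(0, len(motifs))]
        s = s[:p] + m + s[p + 3 :]
        seqs.append(s)
        labels.append(1)
    while len(seqs) < n:
        s = _random_inserts(rng, 1)[0]
        if has_motif(s):
            continue
        seqs.append(s)
        labels.append(0)
    return seqs, np.array(labels)


# ---------------------------------------------------------------------------
# toy trajectories
# ---------------------------------------------------------------------------


def simulate_toy_trajectory(
    n_frames: int = 2000,
    planted_pairs: Sequence[tuple[int, int, float]] = (),
    wobble_sd_nm: float = 0.0,
    seed: int = 0,
    cnt_radius_nm: float = CNT_RADIUS_NM,
    box: tuple[float, float, float] = (20.0, 20.0, 20.759),
) -> Trajectory:
    """Geometric fixture: a 30-nt bead chain wrapped around a cylinder.

    Each nucleotide contributes one backbone and one base bead laid out on a
    helix around the z-axis; tube beads sit exactly on the 0.6-nm-radius
    cylinder.  For every planted pair ``(i, j, radial_offset_nm)`` (1-based
    nucleotide indices, |i-j| >= 2) the two base beads are moved to a common
    site 0.25 nm apart at surface distance *radial_offset_nm*; all other
    base beads stay >= 0.8 nm from any non-neighbour base bead so that the
    3.5-A rule recovers exactly the planted contacts.  This is a geometric
    fixture for the analysis statistics, not simulated physics.
    """
    if n_frames < 1:
        raise GeneratorError("n_frames must be >= 1")
    used: set[int] = set()
    for i, j, off in planted_pairs:
        if abs(i - j) < 2:
            raise GeneratorError(f"planted pair ({i},{j}) must satisfy |i-j| >= 2")
        if off < 0:
            raise GeneratorError("radial_offset must be >= 0")
        if i in used or j in used:
            raise GeneratorError("planted pairs share a nucleotide index")
        if not (1 <= i <= INSERT_LENGTH and 1 <= j <= INSERT_LENGTH):
            raise GeneratorError("planted indices must be in 1..30")
        used.update((i, j))

    rng = np.random.default_rng(seed)
    n_nt = INSERT_LENGTH
    # single-turn helix: one full wrap over the 30 nucleotides, so angular
    # separation grows monotonically with chain separation and non-neighbour
    # base beads never approach each other
    dtheta = 2.0 * np.pi / n_nt
    dz = 0.62
    base_r = cnt_radius_nm + 0.34  # stacked on the sidewall
    bb_r = cnt_radius_nm + 0.85
    z0 = -dz * (n_nt - 1) / 2.0

    rows = []
    base_pos = np.zeros((n_nt, 3))
    bb_pos = np.zeros((n_nt, 3))
    for t in range(n_nt):
        th = t * dtheta
        z = z0 + t * dz
        base_pos[t] = (base_r * np.cos(th), base_r * np.sin(th), z)
        bb_pos[t] = (bb_r * np.cos(th), bb_r * np.sin(th), z)

    # planted sites sit on the opposite side of the cylinder from the helix
    # slot of their first nucleotide, at the prescribed surface offset
    for i, j, off in planted_pairs:
        th = (i - 1) * dtheta + np.pi
        r = cnt_radius_nm + off
        zc = z0 + (i - 1) * dz
        site = np.array([r * np.cos(th), r * np.sin(th), zc])
        base_pos[i - 1] = site + np.array([0.0, 0.0, +0.125])
        base_pos[j - 1] = site + np.array([0.0, 0.0, -0.125])

    # construction check: the planted contacts must be the only base-bead
    # pairs below the clearance, or downstream recovery would be ambiguous
    planted_set = {tuple(sorted((i, j))) for i, j, _ in planted_pairs}
    diff = base_pos[:, None, :] - base_pos[None, :, :]
    Lz = box[2]
    diff[..., 2] -= Lz * np.round(diff[..., 2] / Lz)
    dmat = np.linalg.norm(diff, axis=-1)
    for a in range(n_nt):
        for b in range(a + 1, n_nt):
            if b - a < 2 or (a + 1, b + 1) in planted_set:
                continue
            if dmat[a, b] < 0.8:
                raise GeneratorError(
                    f"planted layout places nucleotides {a+1},{b+1} only "
                    f"{dmat[a, b]:.2f} nm apart; choose other pair indices"
                )

    bases = "ACGT" * 8
    bead_id = 0
    for t in range(n_nt):
        rows.append((bead_id, "backbone", "-", t + 1))
        bead_id += 1
        rows.append((bead_id, "base", bases[t], t + 1))
        bead_id += 1

    # tube beads: rings on the cylinder surface along z
    n_rings, n_per_ring = 12, 8
    cnt_pos = []
    for ridx in range(n_rings):
        z = -box[2] / 2 + (ridx + 0.5) * box[2] / n_rings
        for a in range(n_per_ring):
            th = 2 * np.pi * a / n_per_ring
            cnt_pos.append((cnt_radius_nm * np.cos(th), cnt_radius_nm * np.sin(th), z))
            rows.append((bead_id, "cnt", "-", 0))
            bead_id += 1
    cnt_pos = np.array(cnt_pos)

    static = np.zeros((bead_id, 3))
    for t in range(n_nt):
        static[2 * t] = bb_pos[t]
        static[2 * t + 1] = base_pos[t]
    static[2 * n_nt :] = cnt_pos

    positions = np.repeat(static[None, :, :], n_frames, axis=0)
    if wobble_sd_nm > 0:
        # DNA beads wobble; the rigid tube does not
        noise = rng.normal(0.0, wobble_sd_nm, size=(n_frames, 2 * n_nt, 3))
        positions[:, : 2 * n_nt, :] += noise

    beads = pd.DataFrame(rows, columns=["bead_id", "role", "base", "nt_index"])
    return Trajectory(
        positions=positions,
        beads=beads,
        box=box,
        cnt_radius=cnt_radius_nm,
        axis_point=np.zeros(3),
        axis_dir=np.array([0.0, 0.0, 1.0]),
        periodic_axis=2,
    )


def simulate_random_walk_trajectory(
    n_frames: int,
    n_beads: int = 4,
    step_sd_nm: float = 0.02,
    seed: int = 0,
    box: tuple[float, float, float] = (20.0, 20.0, 20.759),
) -> Trajectory:
    """Free random-walk beads (role 'backbone'): an MSD test fixture."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, step_sd_nm, size=(n_frames - 1, n_beads, 3))
    pos = np.concatenate(
        [np.zeros((1, n_beads, 3)), np.cumsum(steps, axis=0)], axis=0
    )
    beads = pd.DataFrame(
        {
            "bead_id": np.arange(n_beads),
            "role": "backbone",
            "base": "-",
            "nt_index": np.arange(1, n_beads + 1),
        }
    )
    return Trajectory(positions=pos, beads=beads, box=box, periodic_axis=None)


# ---------------------------------------------------------------------------
# library I/O helpers
# ---------------------------------------------------------------------------


def write_library_fasta(
    lib: LibraryRound,
    path: str | Path,
    full_reads: bool = False,
    counts: str = "sidecar",
) -> None:
    """Write a round's library as FASTA.

    ``full_reads`` embeds each insert between the construct's primer
    regions (66-nt reads); counts go to a sidecar TSV (sequence, count)
    or are encoded by record duplication (counts='duplicate').
    """
    from .sequences import FORWARD_PRIMER, REVERSE_REGION

    if counts not in ("sidecar", "duplicate"):
        raise GeneratorError(f"unknown counts mode {counts!r}")
    path = Path(path)
    with open(path, "w") as fh:
        idx = 0
        for rec in lib.records:
            seq = rec.sequence
            if full_reads:
                seq = FORWARD_PRIMER + seq + REVERSE_REGION
            reps = rec.count if counts == "duplicate" else 1
            for _ in range(reps):
                fh.write(f">r{lib.round_index}_s{idx}\n{seq}\n")
                idx += 1
    if counts == "sidecar":
        pd.DataFrame(
            {
                "sequence": [r.sequence for r in lib.records],
                "count": [r.count for r in lib.records],
            }
        ).to_csv(path.with_suffix(".counts.tsv"), sep="\t", index=False)
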
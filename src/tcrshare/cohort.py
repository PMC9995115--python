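"""Synthetic multi-compartment, multi-visit Treg/non-Treg cohorts.

Every downstream analysis is testable against planted ground truth:

* background clonotypes are drawn independently per sample from the
  generative V(D)J model, so cross-sample background sharing arises only from
  convergent recombination (the same high-p_gen junction drawn twice);
* clone sizes follow a Zipf law over ranks with exponent ``alpha``; under
  NEUTRAL selection ranks are assigned by noisy log p_gen score, making clone
  frequency positively coupled to generation probability; under ANTIGEN
  selection planted clones are inserted into a hyper-expanded frequency-rank
  band independently of their p_gen and copied into the configured
  compartments and visits (convergent selection);
* "antigen-driven" similarity-cluster families are planted as a star around a
  13-15 aa seed junction with one substitution per member, split across the
  left and right joint, so the k-mer network rule (k=3, tau=8) must recover
  each family as one cross-compartment component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._codons import AMINO_ACIDS
from .errors import GenerationError, ValidationError
from .io import Repertoire, repertoire_from_counts
from .vdj import RecombinationModel, default_model, pgen_aa_many, sample_junctions

NEUTRAL = "NEUTRAL"
ANTIGEN = "ANTIGEN"


@dataclass(frozen=True)
class PlantedSharedSpec:
    """Clones copied across compartments/visits into a frequency-rank band."""

    n_clones: int = 30
    compartments: tuple[str, ...] = ("SF_LEFT", "SF_RIGHT")
    visits: tuple[int, ...] | None = None  # None = every visit
    rank_band: tuple[int, int] = (1, 100)


@dataclass(frozen=True)
class PlantedClusterSpec:
    """Sequence-similar clone families split across compartments."""

    n_families: int = 6
    family_size: int = 40
    substitutions: int = 1
    #: member -> compartment assignment cycle; "BOTH" plants the member in
    #: every listed compartment (a cross-knee shared clone)
    compartments: tuple[str, ...] = ("SF_LEFT", "SF_RIGHT", "BOTH")
    subset: str = "TREG"
    length_range: tuple[int, int] = (13, 15)
    min_shared_kmers: int = 8


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 2
    compartments: tuple[str, ...] = ("SF_LEFT", "SF_RIGHT")
    subsets: tuple[str, ...] = ("TREG", "NON_TREG")
    visits: int = 2
    repertoire_size: int = 2000
    reads_per_sample: int | None = None  # default 50 × repertoire_size
    alpha: float = 1.5
    selection_mode: str = ANTIGEN
    planted_shared: tuple[PlantedSharedSpec, ...] = (PlantedSharedSpec(),)
    planted_clusters: tuple[PlantedClusterSpec, ...] = (PlantedClusterSpec(),)
    treg_multiplier: float = 2.0
    pgen_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 1:
            raise ValidationError("alpha must be > 1")
        if self.selection_mode not in (NEUTRAL, ANTIGEN):
            raise ValidationError("selection_mode must be NEUTRAL or ANTIGEN")
        if self.visits < 1 or self.n_patients < 1 or self.repertoire_size < 1:
            raise ValidationError("n_patients, visits and repertoire_size must be ≥ 1")
        planted = sum(s.n_clones for s in self.planted_shared) * max(1.0, self.treg_multiplier)
        planted += sum(s.n_families * s.family_size for s in self.planted_clusters)
        if planted > self.repertoire_size:
            raise ValidationError("planted clone count exceeds repertoire_size")
        for spec in self.planted_clusters:
            if spec.substitutions < 1:
                raise ValidationError("substitutions must be ≥ 1")

    @property
    def reads(self) -> int:
        return self.reads_per_sample or 50 * self.repertoire_size


@dataclass
class GroundTruth:
    mode: str
    shared_clone_keys: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    cluster_families: dict[tuple[str, str, int], tuple[str, ...]] = field(default_factory=dict)

    def shared_for(self, patient: str, subset: str) -> set[str]:
        return self.shared_clone_keys.get((patient, subset), set())


def _rng_for(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, *key)))


def sample_unique_productive(
    model: RecombinationModel,
    size: int,
    rng: np.random.Generator,
    exclude: set[str] | None = None,
    max_stall: int = 25,
) -> list[str]:
    """``size`` distinct productive amino-acid junctions (duplicates resampled)."""
    if size < 1:
        raise ValidationError("size must be ≥ 1")
    seen: set[str] = set(exclude or ())
    out: list[str] = []
    stall = 0
    while len(out) < size:
        need = size - len(out)
        draws = sample_junctions(model, max(64, int(1.5 * need)), rng, productive_only=True)
        progress = False
        for _nt, aa in draws:
            if aa not in seen:
                seen.add(aa)
                out.append(aa)
                progress = True
                if len(out) == size:
                    break
        if progress:
            stall = 0
        else:
            stall += 1
            if stall > max_stall:
                raise GenerationError(
                    f"could not collect {size} unique productive junctions "
                    f"({len(out)} found); model support is likely smaller than requested size"
                )
    return out


def generate_random_repertoire(
    model: RecombinationModel,
    size: int,
    seed: int | np.random.Generator,
    sample_id: str = "random",
    compartment: str = "PB",
    subset: str = "TREG",
) -> Repertoire:
    """Size-matched random repertoire: unique productive junctions, each count 1."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    junctions = sample_unique_productive(model, size, rng)
    return repertoire_from_counts(
        ((aa, None, None, 1) for aa in junctions),
        sample_id=sample_id,
        patient="RANDOM",
        compartment=compartment,
        subset=subset,
        visit=0,
    )


def _zipf_counts(size: int, alpha: float, reads: int, rng: np.random.Generator | None = None) -> np.ndarray:
    """Zipf-law counts per rank (1-based): multinomial around r^-alpha weights.

    With ``rng`` the read mass is multinomially distributed over ranks (every
    rank keeps at least one read, so the clonotype is observed); without,
    deterministic quantization is used.
    """
    ranks = np.arange(1, size + 1, dtype=float)
    w = ranks**-alpha
    p = w / w.sum()
    if rng is None:
        counts = np.round(reads * p)
    else:
        counts = rng.multinomial(reads, p)
    return np.maximum(1, counts).astype(np.int64)


def _mutate_family(
    seed_junction: str,
    spec: PlantedClusterSpec,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> list[str]:
    """Star family around a seed: members differ at ``substitutions`` positions
    and are verified to share ≥ min_shared_kmers distinct 3-mers with the seed."""
    from .network import shared_kmer_count  # local import to avoid a cycle

    if len(seed_junction) < spec.min_shared_kmers + 4:
        raise GenerationError(
            f"family seed {seed_junction!r} too short for the ≥{spec.min_shared_kmers} shared 3-mer rule"
        )
    members = [seed_junction]
    seen = {seed_junction}
    while len(members) < spec.family_size:
        for _ in range(max_tries):
            m = list(seed_junction)
            pos = rng.choice(len(m), size=spec.substitutions, replace=False)
            for p in pos:
                choices = [c for c in AMINO_ACIDS if c != m[p]]
                m[p] = choices[rng.integers(len(choices))]
            cand = "".join(m)
            if cand not in seen and shared_kmer_count(cand, seed_junction, 3) >= spec.min_shared_kmers:
                members.append(cand)
                seen.add(cand)
                break
        else:
            raise GenerationError(f"could not grow family around {seed_junction!r}")
    return members


def _family_seed_junction(
    model: RecombinationModel,
    length_range: tuple[int, int],
    rng: np.random.Generator,
    exclude: set[str],
    max_rounds: int = 400,
) -> str:
    lo, hi = length_range
    for _ in range(max_rounds):
        for _nt, aa in sample_junctions(model, 256, rng, productive_only=True):
            if lo <= len(aa) <= hi and aa not in exclude:
                return aa
    raise GenerationError(f"model rarely generates junctions of length {lo}-{hi} aa")


def generate_cohort(config: CohortConfig, model: RecombinationModel | None = None) -> tuple[list[Repertoire], GroundTruth]:
    """Generate the full cohort plus its ground truth. Same seed ⇒ identical cohort."""
    model = model or default_model()
    truth = GroundTruth(mode=config.selection_mode)
    reps: list[Repertoire] = []
    antigen = config.selection_mode == ANTIGEN

    for p_idx in range(config.n_patients):
        patient = f"P{p_idx + 1}"
        for s_idx, subset in enumerate(config.subsets):
            plant_rng = _rng_for(config.seed, 1, p_idx, s_idx)
            shared_plan: list[tuple[str, PlantedSharedSpec, int]] = []
            family_plan: dict[str, list[tuple[str, int]]] = {c: [] for c in config.compartments}
            used: set[str] = set()
            used_ranks: set[int] = set()
            if antigen:
                for spec in config.planted_shared:
                    n = spec.n_clones
                    if subset == "TREG":
                        n = int(round(n * config.treg_multiplier))
                    juncs = sample_unique_productive(model, n, plant_rng, exclude=used)
                    used |= set(juncs)
                    lo, hi = spec.rank_band
                    if hi > config.repertoire_size:
                        raise ValidationError(f"rank band {spec.rank_band} exceeds repertoire_size")
                    for j in juncs:
                        # one rank per clone, shared by every sample it is planted
                        # into: dominant clones keep their dominance across
                        # compartments and visits
                        avail = [r for r in range(lo - 1, hi) if r not in used_ranks]
                        if not avail:
                            raise GenerationError(f"rank band {spec.rank_band} exhausted")
                        r = int(avail[plant_rng.integers(len(avail))])
                        used_ranks.add(r)
                        shared_plan.append((j, spec, r))
                    truth.shared_clone_keys.setdefault((patient, subset), set()).update(juncs)
                for spec in config.planted_clusters:
                    if spec.subset != subset:
                        continue
                    for f_idx in range(spec.n_families):
                        seed_j = _family_seed_junction(model, spec.length_range, plant_rng, used)
                        members = _mutate_family(seed_j, spec, plant_rng)
                        used |= set(members)
                        truth.cluster_families[(patient, subset, f_idx)] = tuple(members)
                        targets = [c for c in spec.compartments if c != "BOTH"]
                        for m_idx, member in enumerate(members):
                            comp = spec.compartments[m_idx % len(spec.compartments)]
                            for c in targets if comp == "BOTH" else (comp,):
                                family_plan[c].append((member, f_idx))

            for c_idx, compartment in enumerate(config.compartments):
                for visit in range(config.visits):
                    rng = _rng_for(config.seed, 2, p_idx, s_idx, c_idx, visit)
                    size = config.repertoire_size
                    counts = _zipf_counts(size, config.alpha, config.reads, rng)

                    planted: list[tuple[str, int]] = []  # (junction, rank index 0-based)
                    taken = np.zeros(size, dtype=bool)
                    if antigen:
                        for j, spec, r in shared_plan:
                            if compartment not in spec.compartments:
                                continue
                            if spec.visits is not None and visit not in spec.visits:
                                continue
                            taken[r] = True
                            planted.append((j, r))
                        fam = family_plan[compartment]
                        tail_lo = size // 2
                        for member, _f in fam:
                            free = np.flatnonzero(~taken[tail_lo:])
                            r = int(free[rng.integers(free.size)]) + tail_lo
                            taken[r] = True
                            planted.append((member, r))

                    n_bg = size - len(planted)
                    exclude = {j for j, _ in planted}
                    background = sample_unique_productive(model, n_bg, rng, exclude=exclude)
                    pgen = pgen_aa_many(model, background)
                    score = np.log10(np.maximum(pgen, 1e-300)) + rng.normal(0.0, config.pgen_noise_sd, n_bg)
                    order = np.argsort(-score, kind="stable")
                    free_ranks = np.flatnonzero(~taken)
                    records = [(j, None, None, int(counts[r])) for j, r in planted]
                    records += [
                        (background[int(i)], None, None, int(counts[int(r)]))
                        for i, r in zip(order, free_ranks)
                    ]
                    reps.append(
                        repertoire_from_counts(
                            records,
                            sample_id=f"{patient}_{subset}_{compartment}_v{visit}",
                            patient=patient,
                            compartment=compartment,
                            subset=subset,
                            visit=visit,
                        )
                    )
    return reps, truth
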
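"""Generative model of TCRβ V(D)J recombination with exact generation probabilities.

The model is deliberately simple: a junction is built as

    (V suffix trimmed from its 3' end) + (i.i.d. inserted nucleotides) + (J prefix
    trimmed from its 5' end)

i.e. the D segment and both insertion zones are collapsed into a single
insertion segment. This preserves the property that analyses here rely on —
short, low-insertion junctions are generated by many independent recombination
events and therefore have high generation probability (convergent
recombination) — while keeping both the dynamic programme and the exhaustive
test oracle tractable.

Generation probability of a nucleotide junction is the exact sum of
``P(V)·P(del_V)·P(ins_len)·Π P(ins_nt)·P(del_J)·P(J)`` over every
recombination scenario whose concatenation equals the query. The amino-acid
level sums that quantity over all coding nucleotide sequences without ever
enumerating codon combinations: fixed V/J-derived positions constrain the
codons, free (inserted) positions contribute their summed nucleotide mass,
and at most two codons straddle a boundary.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np
import yaml

from ._codons import (
    AA_TO_CODONS,
    NT_INDEX,
    NUCLEOTIDES,
    aa_codon_arrays,
    translate,
)
from .errors import FormatError, GenerationError, ValidationError

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class Segment:
    """A germline junction contribution: V 3' suffix or J 5' prefix."""

    name: str
    seq: str
    prob: float


@dataclass(frozen=True)
class PgenRecord:
    sequence: str
    pgen: float
    level: str  # "NT" or "AA"


@dataclass
class RecombinationModel:
    """Parameters of the V–insertion–J generative model.

    ``v_deletion_pmf[d]`` is the probability of trimming ``d`` nucleotides from
    the 3' end of the chosen V suffix; ``j_deletion_pmf`` the same for the 5'
    end of the J prefix. ``insertion_length_pmf[l]`` is the probability of
    inserting ``l`` i.i.d. nucleotides with per-position probabilities
    ``insertion_nt_probs`` (ACGT order).
    """

    v_segments: list[Segment]
    j_segments: list[Segment]
    v_deletion_pmf: np.ndarray
    j_deletion_pmf: np.ndarray
    insertion_length_pmf: np.ndarray
    insertion_nt_probs: np.ndarray
    name: str = "unnamed"
    _caches: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.v_deletion_pmf = np.asarray(self.v_deletion_pmf, dtype=float)
        self.j_deletion_pmf = np.asarray(self.j_deletion_pmf, dtype=float)
        self.insertion_length_pmf = np.asarray(self.insertion_length_pmf, dtype=float)
        self.insertion_nt_probs = np.asarray(self.insertion_nt_probs, dtype=float)
        self.validate()

    # -- validation ----------------------------------------------------------
    def validate(self) -> None:
        for label, segs in (("v_segments", self.v_segments), ("j_segments", self.j_segments)):
            if not segs:
                raise ValidationError(f"{label} is empty")
            for seg in segs:
                if not seg.seq or any(c not in NUCLEOTIDES for c in seg.seq):
                    raise ValidationError(f"{label} {seg.name!r}: invalid sequence {seg.seq!r}")
            total = sum(s.prob for s in segs)
            if abs(total - 1.0) > _PROB_TOL or any(s.prob < 0 for s in segs):
                raise ValidationError(f"{label} usage probabilities must be ≥0 and sum to 1 (got {total})")
        for label, pmf in (
            ("v_deletion_pmf", self.v_deletion_pmf),
            ("j_deletion_pmf", self.j_deletion_pmf),
            ("insertion_length_pmf", self.insertion_length_pmf),
            ("insertion_nt_probs", self.insertion_nt_probs),
        ):
            if pmf.ndim != 1 or pmf.size == 0:
                raise ValidationError(f"{label} must be a non-empty vector")
            if np.any(pmf < 0) or abs(pmf.sum() - 1.0) > _PROB_TOL:
                raise ValidationError(f"{label} must be ≥0 and sum to 1 (got {pmf.sum()})")
        if self.insertion_nt_probs.size != 4:
            raise ValidationError("insertion_nt_probs must have 4 entries (ACGT)")
        min_v = min(len(s.seq) for s in self.v_segments)
        min_j = min(len(s.seq) for s in self.j_segments)
        if self.v_deletion_pmf.size - 1 > min_v:
            raise ValidationError("v deletion support exceeds shortest V suffix")
        if self.j_deletion_pmf.size - 1 > min_j:
            raise ValidationError("j deletion support exceeds shortest J prefix")

    # -- derived, cached -----------------------------------------------------
    @property
    def max_ins(self) -> int:
        return int(self.insertion_length_pmf.size - 1)

    def fingerprint(self) -> str:
        """Stable content hash, used to key p_gen caches."""
        if "fingerprint" not in self._caches:
            blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
            self._caches["fingerprint"] = hashlib.sha256(blob).hexdigest()[:16]
        return self._caches["fingerprint"]

    def _v_remnants(self) -> list[tuple[str, float]]:
        """All (trimmed V suffix, P(V)·P(del)) pairs with positive probability."""
        if "vrem" not in self._caches:
            out = []
            for seg in self.v_segments:
                for d, pd in enumerate(self.v_deletion_pmf):
                    p = seg.prob * pd
                    if p > 0:
                        out.append((seg.seq[: len(seg.seq) - d], p))
            self._caches["vrem"] = out
        return self._caches["vrem"]

    def _j_remnants(self) -> list[tuple[str, float]]:
        if "jrem" not in self._caches:
            out = []
            for seg in self.j_segments:
                for d, pd in enumerate(self.j_deletion_pmf):
                    p = seg.prob * pd
                    if p > 0:
                        out.append((seg.seq[d:], p))
            self._caches["jrem"] = out
        return self._caches["jrem"]

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "v_segments": [{"name": s.name, "suffix": s.seq, "prob": float(s.prob)} for s in self.v_segments],
            "j_segments": [{"name": s.name, "prefix": s.seq, "prob": float(s.prob)} for s in self.j_segments],
            "v_deletions": [float(x) for x in self.v_deletion_pmf],
            "j_deletions": [float(x) for x in self.j_deletion_pmf],
            "insertion_lengths": [float(x) for x in self.insertion_length_pmf],
            "insertion_nt": {c: float(self.insertion_nt_probs[i]) for i, c in enumerate(NUCLEOTIDES)},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RecombinationModel":
        try:
            v = [Segment(s["name"], s["suffix"], float(s["prob"])) for s in d["v_segments"]]
            j = [Segment(s["name"], s["prefix"], float(s["prob"])) for s in d["j_segments"]]
            ins_nt = np.array([d["insertion_nt"][c] for c in NUCLEOTIDES], dtype=float)
            return cls(
                v_segments=v,
                j_segments=j,
                v_deletion_pmf=np.array(d["v_deletions"], dtype=float),
                j_deletion_pmf=np.array(d["j_deletions"], dtype=float),
                insertion_length_pmf=np.array(d["insertion_lengths"], dtype=float),
                insertion_nt_probs=ins_nt,
                name=str(d.get("name", "unnamed")),
            )
        except (KeyError, TypeError) as exc:
            raise FormatError(f"malformed model spec: missing/invalid field {exc}") from exc

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RecombinationModel":
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise FormatError(f"model spec {path} is not a mapping")
        return cls.from_dict(d)


def default_model() -> RecombinationModel:
    """The packaged toy TRB-like model (8 V suffixes, 6 J prefixes)."""
    with resources.files("tcrshare.models").joinpath("toy_trb.yaml").open("r") as fh:
        return RecombinationModel.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def sample_junctions(
    model: RecombinationModel,
    n: int,
    seed: int | np.random.Generator,
    productive_only: bool = False,
    max_rounds: int = 200,
) -> list[tuple[str, str]]:
    """Draw ``n`` independent recombination events as (nt, aa) junction pairs.

    With ``productive_only`` events whose junction length is not a multiple of
    3 or whose translation contains a stop are rejected and redrawn. The aa
    string for an unproductive out-of-frame junction is the translation of the
    longest in-frame prefix, marked with a trailing ``*``-free truncation; it
    is only meaningful for productive junctions.
    """
    if n < 0:
        raise ValidationError("n must be ≥ 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[tuple[str, str]] = []
    if n == 0:
        return out
    v_seqs = [s.seq for s in model.v_segments]
    j_seqs = [s.seq for s in model.j_segments]
    v_probs = np.array([s.prob for s in model.v_segments])
    j_probs = np.array([s.prob for s in model.j_segments])
    rounds = 0
    while len(out) < n:
        rounds += 1
        if rounds > max_rounds:
            raise GenerationError(
                f"could not draw {n} productive junctions in {max_rounds} rounds; "
                "model may generate (almost) no productive junctions"
            )
        m = max(64, int(1.5 * (n - len(out)) * (3.5 if productive_only else 1.0)))
        vi = rng.choice(len(v_seqs), size=m, p=v_probs)
        dv = rng.choice(model.v_deletion_pmf.size, size=m, p=model.v_deletion_pmf)
        ji = rng.choice(len(j_seqs), size=m, p=j_probs)
        dj = rng.choice(model.j_deletion_pmf.size, size=m, p=model.j_deletion_pmf)
        li = rng.choice(model.insertion_length_pmf.size, size=m, p=model.insertion_length_pmf)
        ins_flat = rng.choice(4, size=int(li.sum()), p=model.insertion_nt_probs)
        pos = 0
        for t in range(m):
            if len(out) >= n:
                break
            ins = "".join(NUCLEOTIDES[c] for c in ins_flat[pos : pos + li[t]])
            pos += li[t]
            nt = v_seqs[vi[t]][: len(v_seqs[vi[t]]) - dv[t]] + ins + j_seqs[ji[t]][dj[t] :]
            if len(nt) % 3 != 0:
                if productive_only:
                    continue
                aa = translate(nt[: 3 * (len(nt) // 3)])
            else:
                aa = translate(nt)
            if productive_only and ("*" in aa or not aa):
                continue
            out.append((nt, aa))
    return out


# ---------------------------------------------------------------------------
# Exact p_gen
# ---------------------------------------------------------------------------

def pgen_nt(model: RecombinationModel, nt: str) -> PgenRecord:
    """Exact generation probability of a nucleotide junction."""
    if not nt or any(c not in NUCLEOTIDES for c in nt):
        raise ValidationError(f"nucleotide sequence must be non-empty over ACGT: {nt!r}")
    L = len(nt)
    pmf = model.insertion_length_pmf
    pnt = model.insertion_nt_probs
    # cumulative log-free products of the middle segment probabilities
    total = 0.0
    jrems = [(jr, pj) for jr, pj in model._j_remnants() if nt.endswith(jr)]
    for vrem, pv in model._v_remnants():
        if not nt.startswith(vrem):
            continue
        lv = len(vrem)
        for jrem, pj in jrems:
            li = L - lv - len(jrem)
            if li < 0 or li >= pmf.size or pmf[li] == 0:
                continue
            p_mid = 1.0
            for c in nt[lv : lv + li]:
                p_mid *= pnt[NT_INDEX[c]]
            total += pv * pj * pmf[li] * p_mid
    return PgenRecord(sequence=nt, pgen=total, level="NT")


def _codon_mass(aa: str, fixed: dict[int, str], pnt: np.ndarray) -> float:
    """Σ over codons of ``aa`` consistent with ``fixed`` positions (0..2) of the
    product of insertion nucleotide probabilities over the free positions."""
    mass = 0.0
    for codon in AA_TO_CODONS[aa]:
        contrib = 1.0
        for t in range(3):
            if t in fixed:
                if codon[t] != fixed[t]:
                    contrib = 0.0
                    break
            else:
                contrib *= pnt[NT_INDEX[codon[t]]]
        mass += contrib
    return mass


def pgen_aa_python(model: RecombinationModel, aa: str) -> float:
    """Reference implementation of the amino-acid level generation probability."""
    A = len(aa)
    L = 3 * A
    pmf = model.insertion_length_pmf
    pnt = model.insertion_nt_probs
    total = 0.0
    for vrem, pv in model._v_remnants():
        lv = len(vrem)
        if lv > L:
            continue
        # full codons entirely V-derived must literally encode the aa prefix
        ok = all(vrem[3 * c : 3 * c + 3] in AA_TO_CODONS[aa[c]] for c in range(lv // 3))
        if not ok:
            continue
        for jrem, pj in model._j_remnants():
            lj = len(jrem)
            li = L - lv - lj
            if li < 0 or li >= pmf.size or pmf[li] == 0:
                continue
            q = L - lj  # first J-derived position
            # full codons entirely J-derived
            cj = -(-q // 3)
            if any(jrem[3 * c - q : 3 * c - q + 3] not in AA_TO_CODONS[aa[c]] for c in range(cj, A)):
                continue
            prob_mid = 1.0
            for c in range(lv // 3, A):
                start = 3 * c
                if start >= q:
                    break  # fully J from here on
                fixed: dict[int, str] = {}
                for t in range(3):
                    p = start + t
                    if p < lv:
                        fixed[t] = vrem[p]
                    elif p >= q:
                        fixed[t] = jrem[p - q]
                mass = _codon_mass(aa[c], fixed, pnt) if fixed else _ins_codon_mass(model, aa[c])
                if mass == 0.0:
                    prob_mid = 0.0
                    break
                prob_mid *= mass
            if prob_mid > 0.0:
                total += pv * pj * pmf[li] * prob_mid
    return total


def _ins_codon_mass(model: RecombinationModel, aa: str) -> float:
    """Probability mass of all codons of ``aa`` under the insertion nt law."""
    key = ("insmass", aa)
    if key not in model._caches:
        pnt = model.insertion_nt_probs
        model._caches[key] = sum(
            pnt[NT_INDEX[c0]] * pnt[NT_INDEX[c1]] * pnt[NT_INDEX[c2]]
            for c0, c1, c2 in AA_TO_CODONS[aa]
        )
    return model._caches[key]


# -- numba-accelerated batch path -------------------------------------------

_KERNEL = None


def _kernel_inputs(model: RecombinationModel):
    if "kernel_inputs" not in model._caches:
        vrems = model._v_remnants()
        jrems = model._j_remnants()
        max_v = max(len(s) for s, _ in vrems)
        max_j = max(len(s) for s, _ in jrems)
        vr = np.zeros((len(vrems), max_v), dtype=np.int8)
        vlen = np.zeros(len(vrems), dtype=np.int64)
        vprob = np.zeros(len(vrems), dtype=np.float64)
        for i, (s, p) in enumerate(vrems):
            vlen[i] = len(s)
            vprob[i] = p
            for t, c in enumerate(s):
                vr[i, t] = NT_INDEX[c]
        jr = np.zeros((len(jrems), max_j), dtype=np.int8)
        jlen = np.zeros(len(jrems), dtype=np.int64)
        jprob = np.zeros(len(jrems), dtype=np.float64)
        for i, (s, p) in enumerate(jrems):
            jlen[i] = len(s)
            jprob[i] = p
            for t, c in enumerate(s):
                jr[i, t] = NT_INDEX[c]
        model._caches["kernel_inputs"] = (vr, vlen, vprob, jr, jlen, jprob)
    return model._caches["kernel_inputs"]


def _get_kernel():
    """Compile (once per process) the numba p_gen kernel; None if unavailable."""
    global _KERNEL
    if _KERNEL is not None:
        return _KERNEL
    try:
        import numba
    except ImportError:  # pragma: no cover - numba is a hard dependency normally
        _KERNEL = False
        return _KERNEL

    @numba.njit(cache=False, fastmath=False)
    def kernel(aa_idx, vr, vlen, vprob, jr, jlen, jprob, ins_pmf, pnt, codons_flat, offsets):
        A = aa_idx.size
        L = 3 * A
        total = 0.0
        for i in range(vr.shape[0]):
            lv = vlen[i]
            if lv > L:
                continue
            ok = True
            for c in range(lv // 3):
                found = False
                a = aa_idx[c]
                for k in range(offsets[a], offsets[a + 1]):
                    if (
                        codons_flat[k, 0] == vr[i, 3 * c]
                        and codons_flat[k, 1] == vr[i, 3 * c + 1]
                        and codons_flat[k, 2] == vr[i, 3 * c + 2]
                    ):
                        found = True
                        break
                if not found:
                    ok = False
                    break
            if not ok:
                continue
            for j in range(jr.shape[0]):
                lj = jlen[j]
                li = L - lv - lj
                if li < 0 or li >= ins_pmf.size or ins_pmf[li] == 0.0:
                    continue
                q = L - lj
                cj = (q + 2) // 3
                okj = True
                for c in range(cj, A):
                    found = False
                    a = aa_idx[c]
                    o = 3 * c - q
                    for k in range(offsets[a], offsets[a + 1]):
                        if (
                            codons_flat[k, 0] == jr[j, o]
                            and codons_flat[k, 1] == jr[j, o + 1]
                            and codons_flat[k, 2] == jr[j, o + 2]
                        ):
                            found = True
                            break
                    if not found:
                        okj = False
                        break
                if not okj:
                    continue
                prob_mid = 1.0
                for c in range(lv // 3, A):
                    start = 3 * c
                    if start >= q:
                        break
                    a = aa_idx[c]
                    mass = 0.0
                    for k in range(offsets[a], offsets[a + 1]):
                        contrib = 1.0
                        for t in range(3):
                            p = start + t
                            ch = codons_flat[k, t]
                            if p < lv:
                                if vr[i, p] != ch:
                                    contrib = 0.0
                                    break
                            elif p >= q:
                                if jr[j, p - q] != ch:
                                    contrib = 0.0
                                    break
                            else:
                                contrib *= pnt[ch]
                        mass += contrib
                    if mass == 0.0:
                        prob_mid = 0.0
                        break
                    prob_mid *= mass
                if prob_mid > 0.0:
                    total += vprob[i] * jprob[j] * ins_pmf[li] * prob_mid
        return total

    _KERNEL = kernel
    return _KERNEL


def pgen_aa(model: RecombinationModel, aa: str, backend: str = "auto") -> PgenRecord:
    """Exact amino-acid level generation probability (sum over coding nt)."""
    if not aa or any(c not in AA_TO_CODONS or c == "*" for c in aa):
        raise ValidationError(f"amino-acid sequence must be non-empty over the 20-letter alphabet: {aa!r}")
    cache = model._caches.setdefault("pgen_aa", {})
    if aa in cache:
        return PgenRecord(sequence=aa, pgen=cache[aa], level="AA")
    kernel = _get_kernel() if backend in ("auto", "numba") else False
    if backend == "numba" and not kernel:
        raise ValidationError("numba backend requested but numba is unavailable")
    if kernel:
        _, _, aa_index = aa_codon_arrays()
        codons_flat, offsets, _ = aa_codon_arrays()
        aa_idx = np.array([aa_index[c] for c in aa], dtype=np.int64)
        vr, vlen, vprob, jr, jlen, jprob = _kernel_inputs(model)
        value = float(
            kernel(
                aa_idx, vr, vlen, vprob, jr, jlen, jprob,
                model.insertion_length_pmf, model.insertion_nt_probs,
                codons_flat, offsets,
            )
        )
    else:
        value = pgen_aa_python(model, aa)
    cache[aa] = value
    return PgenRecord(sequence=aa, pgen=value, level="AA")


def pgen_aa_many(model: RecombinationModel, sequences: Iterable[str], backend: str = "auto") -> np.ndarray:
    """Vector of p_gen values for many amino-acid junctions (cached per model)."""
    return np.array([pgen_aa(model, s, backend=backend).pgen for s in sequences], dtype=float)


# ---------------------------------------------------------------------------
# Exhaustive oracle
# ---------------------------------------------------------------------------

def count_scenarios(model: RecombinationModel) -> int:
    """Number of positive-probability recombination scenarios of the model."""
    nv = sum(1 for s in model.v_segments if s.prob > 0) * int(np.count_nonzero(model.v_deletion_pmf))
    nj = sum(1 for s in model.j_segments if s.prob > 0) * int(np.count_nonzero(model.j_deletion_pmf))
    n_ins = sum(4**li for li, p in enumerate(model.insertion_length_pmf) if p > 0)
    return nv * nj * n_ins


def enumerate_pgen_oracle(model: RecombinationModel, cap: int = 10**6) -> dict[str, float]:
    """Brute-force enumeration of every scenario, accumulated per nt junction.

    Independent of the dynamic-programming path: used as the correctness oracle
    for :func:`pgen_nt` / :func:`pgen_aa` on small models.
    """
    n = count_scenarios(model)
    if n > cap:
        raise ValidationError(f"model has {n} scenarios, above the enumeration cap {cap}")
    pnt = model.insertion_nt_probs
    out: dict[str, float] = {}

    def insertions(length: int):
        if length == 0:
            yield "", 1.0
            return
        for prefix, p in insertions(length - 1):
            for ci, c in enumerate(NUCLEOTIDES):
                yield prefix + c, p * pnt[ci]

    for vseg in model.v_segments:
        if vseg.prob == 0:
            continue
        for dv, pdv in enumerate(model.v_deletion_pmf):
            if pdv == 0:
                continue
            vrem = vseg.seq[: len(vseg.seq) - dv]
            for li, pli in enumerate(model.insertion_length_pmf):
                if pli == 0:
                    continue
                for ins, pins in insertions(li):
                    for jseg in model.j_segments:
                        if jseg.prob == 0:
                            continue
                        for dj, pdj in enumerate(model.j_deletion_pmf):
                            if pdj == 0:
                                continue
                            jrem = jseg.seq[dj:]
                            nt = vrem + ins + jrem
                            p = vseg.prob * pdv * pli * pins * jseg.prob * pdj
                            out[nt] = out.get(nt, 0.0) + p
    return out


def enumerate_pgen_aa_oracle(model: RecombinationModel, cap: int = 10**6) -> dict[str, float]:
    """Oracle p_gen per productive amino-acid junction (in-frame, no stop)."""
    out: dict[str, float] = {}
    for nt, p in enumerate_pgen_oracle(model, cap=cap).items():
        if len(nt) % 3 != 0:
            continue
        aa = translate(nt)
        if "*" in aa or not aa:
            continue
        out[aa] = out.get(aa, 0.0) + p
    return out
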
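"""Methyl chemical-shift vector analysis of polymerase conformational states.

DNA polymerase beta closes its fingers subdomain when it binds a correct
nucleotide.  In an ILV methyl HMQC spectrum each methyl resonance moves from
its "open" (binary) position to its "closed" (correct ternary) position along
a characteristic two-dimensional path in the (1H, 13C) shift plane.  This
module treats the open-to-closed displacement of each methyl as a reference
vector and asks, for any test state (a mutant, a mispaired ternary complex,
...), whether that resonance has moved *along* the closure vector
(on-pathway), *away* from it (off-pathway), or not significantly at all.

Per peak the analysis reports:

* the combined 1H/13C shift change used for the significance filter,
  ``sqrt((d_H^2 + d_C^2/4) / 2)``;
* the vector magnitude ``sqrt(d_H^2 + (0.2514*d_C)^2)`` and from it the
  normalized magnitude ``delta_n = |test - open| / |closed - open|``
  (1 means fully closed);
* ``cos(theta)`` between the test and reference vectors in the carbon-scaled
  plane (1 means exactly along the closure path);
* a classification (on-pathway / off-pathway / not significant) from the
  significance threshold (default 0.025 ppm, strict) and the cosine cutoff
  (default 0.8; values below 0.8 are off-pathway).

Closure of a whole state is summarized by ``RMSD_1.0``, the RMS distance of
the per-peak ``(cos(theta), delta_n)`` pairs from the fully-closed point
(1, 1), globally and per subdomain (lyase, thumb, palm, fingers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "CARBON_SCALE",
    "DEGENERATE_TOL",
    "MethylPeak",
    "MethylPeakList",
    "ShiftVector",
    "ResidueComparison",
    "SubdomainMap",
    "StateComparison",
    "combined_shift",
    "vector_magnitude",
    "normalized_magnitude",
    "cos_theta",
    "rmsd_one",
    "significance_threshold",
    "classify_residue",
    "compare_states",
    "rereference",
    "DEFAULT_SUBDOMAINS",
]

#: Carbon scaling applied to 13C shift differences in all vector geometry.
CARBON_SCALE = 0.2514

#: Reference vectors shorter than this (ppm, scaled plane) are degenerate:
#: delta_n and cos(theta) are undefined for them.
DEGENERATE_TOL = 1e-6

Classification = Literal[
    "on_pathway", "off_pathway", "not_significant", "reference_degenerate"
]


class ShiftVecError(ValueError):
    """Invalid input to a shift-vector operation."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MethylPeak:
    """One methyl resonance of one enzyme state.

    Non-stereospecifically assigned Leu/Val methyls appear as two peaks with
    distinct ``methyl_id`` and are treated as independent measurements.
    """

    residue_number: int
    residue_type: str  # I, L or V
    methyl_id: str
    delta_H: float  # ppm
    delta_C: float  # ppm

    def __post_init__(self) -> None:
        if self.residue_number < 1:
            raise ShiftVecError(f"residue_number must be >= 1, got {self.residue_number}")
        if self.residue_type not in ("I", "L", "V"):
            raise ShiftVecError(f"residue_type must be I, L or V, got {self.residue_type!r}")
        if not (math.isfinite(self.delta_H) and math.isfinite(self.delta_C)):
            raise ShiftVecError("chemical shifts must be finite")

    @property
    def key(self) -> tuple[int, str]:
        return (self.residue_number, self.methyl_id)


@dataclass
class MethylPeakList:
    """A named collection of methyl peaks (one enzyme state)."""

    state_name: str
    peaks: list[MethylPeak]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ShiftVecError(f"peak list {self.state_name!r} is empty")
        keys = [p.key for p in self.peaks]
        if len(set(keys)) != len(keys):
            dup = sorted({k for k in keys if keys.count(k) > 1})
            raise ShiftVecError(f"duplicate peak keys in {self.state_name!r}: {dup}")

    def __len__(self) -> int:
        return len(self.peaks)

    def by_key(self) -> dict[tuple[int, str], MethylPeak]:
        return {p.key: p for p in self.peaks}


@dataclass(frozen=True)
class ShiftVector:
    """A 2D chemical-shift displacement (ppm) with its scaled magnitude."""

    d_H: float
    d_C: float

    @property
    def magnitude(self) -> float:
        return vector_magnitude(self.d_H, self.d_C)

    @property
    def scaled(self) -> tuple[float, float]:
        """Coordinates in the carbon-scaled plane used for all geometry."""
        return (self.d_H, CARBON_SCALE * self.d_C)


@dataclass(frozen=True)
class ResidueComparison:
    """Per-peak vector metrics of a test state against the open/closed pair."""

    peak_key: tuple[int, str]
    residue_type: str
    combined_shift: float
    delta_n: float | None
    cos_theta: float | None
    classification: Classification
    subdomain: str | None = None


@dataclass(frozen=True)
class SubdomainMap:
    """Ordered, non-overlapping residue ranges naming enzyme subdomains."""

    ranges: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        seen: list[tuple[int, int]] = []
        for name, lo, hi in self.ranges:
            if lo > hi:
                raise ShiftVecError(f"subdomain {name}: range [{lo}, {hi}] is inverted")
            for plo, phi in seen:
                if lo <= phi and hi >= plo:
                    raise ShiftVecError(f"subdomain ranges overlap at {name}")
            seen.append((lo, hi))

    def assign(self, residue_number: int) -> str:
        for name, lo, hi in self.ranges:
            if lo <= residue_number <= hi:
                return name
        raise ShiftVecError(f"residue {residue_number} maps to no subdomain")


#: Default subdomain boundaries for the 335-residue polymerase: 8-kDa lyase
#: domain then thumb, palm (with catalytic D190/D192/D256) and fingers
#: (I277, R283) of the 31-kDa polymerase domain.
DEFAULT_SUBDOMAINS = SubdomainMap(
    ranges=(
        ("lyase", 1, 87),
        ("thumb", 88, 151),
        ("palm", 152, 262),
        ("fingers", 263, 335),
    )
)


@dataclass
class StateComparison:
    """Full comparison of one test state against open/closed references."""

    test_state: str
    reference_open: str
    reference_closed: str
    rows: list[ResidueComparison]
    rmsd_global: float | None
    rmsd_by_subdomain: dict[str, float | None]
    counts: dict[str, int]
    mean_delta_n: float | None
    mean_cos_theta: float | None
    unmatched_keys: list[tuple[int, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def _require_finite(*values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ShiftVecError(f"non-finite input: {v!r}")


def combined_shift(d_H: float, d_C: float) -> float:
    """Combined 1H/13C chemical-shift change, sqrt((dH^2 + dC^2/4)/2) ppm.

    This is the quantity the 0.025 ppm significance threshold applies to;
    the carbon term carries the conventional 1/2 shift scaling (1/4 on the
    square).
    """
    _require_finite(d_H, d_C)
    return math.sqrt((d_H * d_H + 0.25 * d_C * d_C) / 2.0)


def vector_magnitude(d_H: float, d_C: float) -> float:
    """Length of the shift vector in the carbon-scaled plane (ppm)."""
    _require_finite(d_H, d_C)
    return math.hypot(d_H, CARBON_SCALE * d_C)


def normalized_magnitude(
    experimental: ShiftVector, reference: ShiftVector, *, tol: float = DEGENERATE_TOL
) -> float:
    """delta_n = |experimental| / |reference|; 1 means fully closed.

    Raises :class:`DegenerateReference` if the reference vector is shorter
    than ``tol`` (the ratio is undefined there).
    """
    ref_mag = reference.magnitude
    if ref_mag < tol:
        raise DegenerateReference(f"reference magnitude {ref_mag:.2e} < tol {tol:.0e}")
    return experimental.magnitude / ref_mag


def cos_theta(
    experimental: ShiftVector, reference: ShiftVector, *, tol: float = DEGENERATE_TOL
) -> float:
    """Cosine of the angle between the two vectors in the scaled plane."""
    e = experimental.scaled
    r = reference.scaled
    e_mag = math.hypot(*e)
    r_mag = math.hypot(*r)
    if e_mag < tol or r_mag < tol:
        raise DegenerateReference("degenerate vector in cos_theta")
    c = (e[0] * r[0] + e[1] * r[1]) / (e_mag * r_mag)
    return max(-1.0, min(1.0, c))


class DegenerateReference(ShiftVecError):
    """Reference (or test) vector too short for delta_n / cos(theta)."""


def rmsd_one(rows: Iterable[tuple[float, float]]) -> float:
    """RMS distance of (cos theta, delta_n) pairs from the closed point (1, 1).

    Zero iff every pair is exactly (1, 1) — fully closed, fully on-pathway.
    """
    arr = np.asarray(list(rows), dtype=float)
    if arr.size == 0:
        raise ShiftVecError("rmsd_one needs at least one (cos_theta, delta_n) row")
    dev = (1.0 - arr[:, 0]) ** 2 + (1.0 - arr[:, 1]) ** 2
    return float(np.sqrt(dev.mean()))


def significance_threshold(
    replicate_groups: Sequence[Sequence[MethylPeakList]],
    factor: float = 1.5,
    *,
    pairing: Literal["within", "between"] = "within",
) -> float:
    """Significance threshold from replicate spectra of unliganded enzyme.

    The threshold is ``factor`` (default 1.5) times the average per-peak
    combined shift over replicate pairs.  ``pairing="within"`` averages over
    all pairs drawn within each group (replicates of the same enzyme);
    ``"between"`` pairs lists across the first two groups.
    """
    if factor < 0:
        raise ShiftVecError("factor must be >= 0")
    pairs: list[tuple[MethylPeakList, MethylPeakList]] = []
    if pairing == "within":
        for group in replicate_groups:
            for i in range(len(group)):
                for j in range(i + 1, len(group)):
                    pairs.append((group[i], group[j]))
    elif pairing == "between":
        if len(replicate_groups) < 2:
            raise ShiftVecError("between-group pairing needs two groups")
        for a in replicate_groups[0]:
            for b in replicate_groups[1]:
                pairs.append((a, b))
    else:
        raise ShiftVecError(f"unknown pairing {pairing!r}")
    if not pairs:
        raise ShiftVecError("need at least 2 replicates in some group")

    shifts: list[float] = []
    for a, b in pairs:
        bk = b.by_key()
        for peak in a.peaks:
            other = bk.get(peak.key)
            if other is not None:
                shifts.append(
                    combined_shift(peak.delta_H - other.delta_H, peak.delta_C - other.delta_C)
                )
    if not shifts:
        raise ShiftVecError("replicate lists share no peaks")
    return factor * float(np.mean(shifts))


def classify_residue(
    combined: float,
    cos_th: float | None,
    threshold: float = 0.025,
    cos_cutoff: float = 0.8,
) -> Classification:
    """Classify one peak from its combined shift and cos(theta).

    Significance is strict (``combined`` must exceed ``threshold``); a
    significant peak is off-pathway only if cos(theta) falls strictly below
    ``cos_cutoff`` — the boundary value itself counts as on-pathway.
    """
    if threshold < 0:
        raise ShiftVecError("threshold must be >= 0")
    if not (-1.0 < cos_cutoff < 1.0):
        raise ShiftVecError("cos_cutoff must lie in (-1, 1)")
    if combined <= threshold:
        return "not_significant"
    if cos_th is None:
        return "reference_degenerate"
    return "on_pathway" if cos_th >= cos_cutoff else "off_pathway"


def rereference(
    peaklist: MethylPeakList,
    anchor: tuple[int, str],
    reference: MethylPeakList,
) -> MethylPeakList:
    """Shift all peaks so the anchor peak coincides with its reference position.

    Mirrors internal referencing to a resonance that is insensitive to ligand
    binding (V221 in this enzyme): the anchor's apparent displacement is
    instrumental and is subtracted from every peak.
    """
    try:
        test_anchor = peaklist.by_key()[anchor]
        ref_anchor = reference.by_key()[anchor]
    except KeyError as exc:
        raise ShiftVecError(f"anchor {anchor} absent from a peak list") from exc
    off_H = test_anchor.delta_H - ref_anchor.delta_H
    off_C = test_anchor.delta_C - ref_anchor.delta_C
    shifted = [
        MethylPeak(p.residue_number, p.residue_type, p.methyl_id, p.delta_H - off_H, p.delta_C - off_C)
        for p in peaklist.peaks
    ]
    return MethylPeakList(state_name=peaklist.state_name, peaks=shifted)


# ---------------------------------------------------------------------------
# full-state comparison
# ---------------------------------------------------------------------------


def compare_states(
    test: MethylPeakList,
    open_ref: MethylPeakList,
    closed_ref: MethylPeakList,
    subdomains: SubdomainMap = DEFAULT_SUBDOMAINS,
    threshold: float = 0.025,
    cos_cutoff: float = 0.8,
    *,
    rmsd_over: Literal["significant", "all_matched"] = "significant",
    degenerate_tol: float = DEGENERATE_TOL,
) -> StateComparison:
    """Compare a test state against the open/closed reference pair.

    For each peak present in all three lists the reference vector is
    ``closed - open`` and the experimental vector is ``test - open`` (the
    open-state resonance is the origin).  Per-peak metrics and classes are
    collected, and RMSD_1.0 is computed globally and per subdomain over the
    significant, non-degenerate rows (or all matched rows when
    ``rmsd_over="all_matched"``).

    Peaks of the test list missing from either reference are reported in
    ``unmatched_keys`` and excluded.
    """
    open_by = open_ref.by_key()
    closed_by = closed_ref.by_key()

    rows: list[ResidueComparison] = []
    unmatched: list[tuple[int, str]] = []
    for peak in test.peaks:
        o = open_by.get(peak.key)
        c = closed_by.get(peak.key)
        if o is None or c is None:
            unmatched.append(peak.key)
            continue
        ref_vec = ShiftVector(c.delta_H - o.delta_H, c.delta_C - o.delta_C)
        exp_vec = ShiftVector(peak.delta_H - o.delta_H, peak.delta_C - o.delta_C)
        comb = combined_shift(exp_vec.d_H, exp_vec.d_C)
        # delta_n only needs a non-degenerate reference; the angle also
        # needs a non-zero experimental vector (a fully open test state has
        # delta_n = 0 but no defined direction)
        try:
            dn = normalized_magnitude(exp_vec, ref_vec, tol=degenerate_tol)
        except DegenerateReference:
            dn = None
        try:
            ct = cos_theta(exp_vec, ref_vec, tol=degenerate_tol)
        except DegenerateReference:
            ct = None
        cls = classify_residue(comb, ct, threshold, cos_cutoff)
        rows.append(
            ResidueComparison(
                peak_key=peak.key,
                residue_type=peak.residue_type,
                combined_shift=comb,
                delta_n=dn,
                cos_theta=ct,
                classification=cls,
                subdomain=subdomains.assign(peak.residue_number),
            )
        )
    if not rows:
        raise ShiftVecError(
            f"no common peaks between {test.state_name!r} and the references"
        )

    def _eligible(r: ResidueComparison) -> bool:
        if r.delta_n is None or r.cos_theta is None:
            return False
        if rmsd_over == "significant":
            return r.classification in ("on_pathway", "off_pathway")
        return True

    def _rmsd(selected: list[ResidueComparison]) -> float | None:
        pts = [(r.cos_theta, r.delta_n) for r in selected if _eligible(r)]
        return rmsd_one(pts) if pts else None

    eligible_rows = [r for r in rows if _eligible(r)]
    by_sub: dict[str, float | None] = {}
    for name, _, _ in subdomains.ranges:
        by_sub[name] = _rmsd([r for r in rows if r.subdomain == name])

    counts = {
        "n_on_pathway": sum(r.classification == "on_pathway" for r in rows),
        "n_off_pathway": sum(r.classification == "off_pathway" for r in rows),
        "n_not_significant": sum(r.classification == "not_significant" for r in rows),
        "n_reference_degenerate": sum(
            r.classification == "reference_degenerate" for r in rows
        ),
    }

    if eligible_rows:
        mean_dn = float(np.mean([r.delta_n for r in eligible_rows]))
        mean_ct = float(np.mean([r.cos_theta for r in eligible_rows]))
    else:
        mean_dn = mean_ct = None

    return StateComparison(
        test_state=test.state_name,
        reference_open=open_ref.state_name,
        reference_closed=closed_ref.state_name,
        rows=rows,
        rmsd_global=_rmsd(rows),
        rmsd_by_subdomain=by_sub,
        counts=counts,
        mean_delta_n=mean_dn,
        mean_cos_theta=mean_ct,
        unmatched_keys=unmatched,
    )
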
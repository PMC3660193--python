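"""Forward simulation of meiosis and mapping-population genotypes.

Two mating designs are supported, mirroring the classical designs used for
linkage mapping in outcrossing trees:

* ``CP`` — a two-way pseudo-testcross: a full-sib family from two unrelated,
  highly heterozygous parents.  Loci heterozygous in exactly one parent
  segregate 1:1 and are informative for that parent only; loci heterozygous
  in both segregate 1:2:1.
* ``F2_SELF`` — a selfed F1 hybrid.  Every heterozygous locus segregates
  1:2:1 in the offspring, and each F1 haplotype traces back to one
  grandparent, so zygotic selection against one grandparental homozygote
  produces clustered segregation distortion.

Crossovers are drawn per linkage group as a Poisson count-location process
(no chiasma interference): the count is Poisson with mean equal to the
linkage-group length in Morgans, and locations are uniform — both on a
"warped" distance scale obtained by integrating a per-parent piecewise
constant recombination-rate modifier track.  A modifier of 2.0 over an
interval makes that interval recombine like one twice as long.

An optional viability locus removes zygotes after fertilisation: each
offspring survives with the fitness of its genotype class at the locus
(classes keyed by the number of haplotype-1 alleles carried: "AA", "AB",
"BB").  Sampling rejects non-survivors until the requested family size is
reached, so the delivered family is the post-selection one, as in a real
nursery.  A per-offspring truth record (crossover counts, haplotype origins,
pre-error calls) is kept for downstream power studies.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ViabilityLocus",
    "TrueMap",
    "CrossDesign",
    "GenotypeMatrix",
    "uniform_true_map",
    "simulate_gamete",
    "simulate_cross",
    "write_genotypes",
    "read_genotypes",
]

MISSING = "U"
F2_CODES = ("A", "H", "B")  # hom haplotype-0 allele / het / hom haplotype-1 allele


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class ViabilityLocus:
    """Zygotic viability locus with per-genotype-class fitness in [0, 1].

    Classes are keyed "AA"/"AB"/"BB" by the count of haplotype-1 alleles the
    zygote carries at the locus position (for a selfed F1, haplotype 1 is one
    grandparental chromosome, so "BB" is one grandparental homozygote).
    """

    lg: str
    position: float
    fitness: Mapping[str, float]

    def __post_init__(self) -> None:
        vals = [self.fitness.get(c, 1.0) for c in ("AA", "AB", "BB")]
        if any(not (0.0 <= v <= 1.0) for v in vals):
            raise ConfigurationError("fitness values must lie in [0, 1]")
        if max(vals) < 1.0:
            raise ConfigurationError("at least one genotype class must have fitness 1.0")
        if max(vals) == 0.0:
            raise ConfigurationError("all fitness values are 0: no offspring can survive")


@dataclass
class TrueMap:
    """Ground-truth genetic map driving the simulator.

    Parameters
    ----------
    linkage_groups
        ``[(lg_id, length_cM), ...]``.
    markers
        DataFrame with columns ``marker``, ``lg``, ``position`` (cM, 0-based
        from the LG start), ``contig``.
    rate_modifiers
        Optional per-parent piecewise-constant recombination-rate multiplier
        tracks: ``{parent_id: {lg_id: [(start, end, mult), ...]}}`` over
        half-open cM intervals.  1.0 is baseline; values > 1 are local
        recombination hotspots, values < 1 coldspots.
    viability_locus
        Optional post-zygotic selection locus.
    """

    linkage_groups: list[tuple[str, float]]
    markers: pd.DataFrame
    rate_modifiers: dict[str, dict[str, list[tuple[float, float, float]]]] = field(
        default_factory=dict
    )
    viability_locus: ViabilityLocus | None = None

    def __post_init__(self) -> None:
        lengths = dict(self.linkage_groups)
        if not set(self.markers["lg"]).issubset(lengths):
            raise ConfigurationError("marker assigned to unknown linkage group")
        for lg, grp in self.markers.groupby("lg"):
            if (grp["position"] < 0).any() or (grp["position"] > lengths[lg]).any():
                raise ConfigurationError(f"marker position outside [0, length] on {lg}")
        for parent, tracks in self.rate_modifiers.items():
            for lg, track in tracks.items():
                self._check_track(lg, track, lengths[lg], parent)
        if self.viability_locus is not None and self.viability_locus.lg not in lengths:
            raise ConfigurationError("viability locus on unknown linkage group")

    @staticmethod
    def _check_track(lg: str, track, length: float, parent: str) -> None:
        pos = 0.0
        for start, end, mult in sorted(track):
            if mult <= 0:
                raise ConfigurationError(f"non-positive modifier on {lg} for {parent}")
            if start > pos + 1e-9:
                raise ConfigurationError(
                    f"modifier track for {parent} leaves gap [{pos}, {start}) on {lg}"
                )
            pos = max(pos, end)
        if pos < length - 1e-9:
            raise ConfigurationError(
                f"modifier track for {parent} does not reach the end of {lg}"
            )

    def lg_length(self, lg: str) -> float:
        return dict(self.linkage_groups)[lg]

    def track(self, parent: str, lg: str) -> list[tuple[float, float, float]]:
        default = [(0.0, self.lg_length(lg), 1.0)]
        return self.rate_modifiers.get(parent, {}).get(lg, default)


@dataclass
class CrossDesign:
    """A mating design: parents as phased haplotypes plus a family size.

    ``parents`` maps parent id to a ``(2, n_markers)`` int array of alleles
    (0/1), rows being the two phased haplotypes, columns following the row
    order of ``TrueMap.markers``.  CP needs two parents; F2_SELF exactly one
    (the F1 hybrid whose haplotype 0/1 identify the two grandparents).
    """

    design: str  # "CP" | "F2_SELF"
    parents: dict[str, np.ndarray]
    n_offspring: int
    seed: int

    def __post_init__(self) -> None:
        if self.design not in ("CP", "F2_SELF"):
            raise ConfigurationError(f"unknown design {self.design!r}")
        need = 2 if self.design == "CP" else 1
        if len(self.parents) != need:
            raise ConfigurationError(f"{self.design} needs exactly {need} parent(s)")
        if self.n_offspring < 1:
            raise ConfigurationError("n_offspring must be >= 1")


@dataclass
class GenotypeMatrix:
    """Offspring genotype calls plus marker metadata and (optional) truth.

    ``calls`` is markers x individuals with codes "A"/"H"/"B"/"U"; which
    codes are legal at a marker depends on its segregation type (``seg_type``
    column of ``markers``: "1:2:1", "1:1-mat", "1:1-pat", or "uninf").
    """

    population_type: str  # "CP" | "F2"
    calls: pd.DataFrame
    markers: pd.DataFrame  # marker, lg, position, contig, seg_type (indexed like calls)
    truth: dict | None = None

    @property
    def n_offspring(self) -> int:
        return self.calls.shape[1]

    def counts(self, marker: str) -> dict[str, int]:
        """Non-missing genotype-class counts at one marker."""
        vc = self.calls.loc[marker].value_counts()
        return {c: int(vc.get(c, 0)) for c in F2_CODES}


def uniform_true_map(
    n_lg: int = 12,
    length_cM: float = 120.0,
    spacing_cM: float = 10.0,
    contig_copies: int = 1,
    rate_modifiers: dict | None = None,
    viability_locus: ViabilityLocus | None = None,
) -> TrueMap:
    """Evenly spaced ground-truth map, one contig per site (or several copies
    of the same contig when ``contig_copies`` > 1, for error-rate studies)."""
    lgs = [(f"LG{i + 1}", float(length_cM)) for i in range(n_lg)]
    rows = []
    for lg, L in lgs:
        positions = np.arange(0.0, L + 1e-9, spacing_cM)
        for j, pos in enumerate(positions):
            for c in range(contig_copies):
                rows.append(
                    (f"{lg}_m{j:03d}" + (f"_{c}" if contig_copies > 1 else ""),
                     lg, float(pos), f"ctg_{lg}_{j:03d}")
                )
    markers = pd.DataFrame(rows, columns=["marker", "lg", "position", "contig"])
    return TrueMap(lgs, markers, rate_modifiers or {}, viability_locus)


def _warp(track: Sequence[tuple[float, float, float]]):
    """Cumulative warped distance at the physical breakpoints of a track."""
    track = sorted(track)
    starts = np.array([t[0] for t in track])
    ends = np.array([t[1] for t in track])
    mults = np.array([t[2] for t in track])
    seg_w = (ends - starts) * mults
    cum_w = np.concatenate([[0.0], np.cumsum(seg_w)])
    return starts, ends, mults, cum_w


def _warped_position(x: float, starts, ends, mults, cum_w) -> float:
    i = int(np.searchsorted(ends, x, side="left"))
    i = min(i, len(ends) - 1)
    return float(cum_w[i] + (x - starts[i]) * mults[i])


def _physical_position(w: float, starts, ends, mults, cum_w) -> float:
    i = int(np.searchsorted(cum_w[1:], w, side="left"))
    i = min(i, len(ends) - 1)
    return float(starts[i] + (w - cum_w[i]) / mults[i])


def simulate_gamete(
    parent_haplotypes: np.ndarray,
    true_map: TrueMap,
    parent_id: str,
    rng: np.random.Generator,
):
    """Draw one gamete from a phased parent.

    Returns ``(alleles, events)`` where ``alleles`` is an int array over all
    map markers (row order of ``true_map.markers``) and ``events`` maps lg id
    to ``(start_haplotype, breakpoints_cM)`` — enough to recover the
    haplotype origin at any position, e.g. at a viability locus.

    Crossover counts are Poisson with mean = warped LG length in Morgans;
    locations are uniform on the warped scale and mapped back to physical cM.
    """
    alleles = np.empty(len(true_map.markers), dtype=np.int8)
    events: dict[str, tuple[int, np.ndarray]] = {}
    mk = true_map.markers
    for lg, _length in true_map.linkage_groups:
        starts, ends, mults, cum_w = _warp(true_map.track(parent_id, lg))
        warped_len = cum_w[-1]
        n_co = rng.poisson(warped_len / 100.0)
        if n_co:
            w_locs = np.sort(rng.uniform(0.0, warped_len, size=n_co))
            breaks = np.array(
                [_physical_position(w, starts, ends, mults, cum_w) for w in w_locs]
            )
        else:
            breaks = np.empty(0)
        start_hap = int(rng.integers(2))
        events[lg] = (start_hap, breaks)
        idx = np.flatnonzero((mk["lg"] == lg).to_numpy())
        if idx.size:
            pos = mk["position"].to_numpy()[idx]
            hap = (start_hap + np.searchsorted(breaks, pos, side="right")) % 2
            alleles[idx] = parent_haplotypes[hap, idx]
    return alleles, events


def _origin_at(events: dict, lg: str, position: float) -> int:
    start_hap, breaks = events[lg]
    return (start_hap + int(np.searchsorted(breaks, position, side="right"))) % 2


def _seg_types(design: CrossDesign, n_markers: int) -> np.ndarray:
    parents = list(design.parents.values())
    if design.design == "F2_SELF":
        het = parents[0][0] != parents[0][1]
        return np.where(het, "1:2:1", "uninf")
    mom, dad = parents
    mom_het = mom[0] != mom[1]
    dad_het = dad[0] != dad[1]
    out = np.full(n_markers, "uninf", dtype=object)
    out[mom_het & ~dad_het] = "1:1-mat"
    out[~mom_het & dad_het] = "1:1-pat"
    out[mom_het & dad_het] = "1:2:1"
    return out.astype(str)


def _legal_codes(design: CrossDesign, n_markers: int) -> list[tuple[str, ...]]:
    """Possible (non-missing) genotype codes per marker given the parents."""
    parents = list(design.parents.values())
    if design.design == "F2_SELF":
        parents = [parents[0], parents[0]]
    mom, dad = parents
    legal = []
    for j in range(n_markers):
        sums = {int(a + b) for a in mom[:, j] for b in dad[:, j]}
        legal.append(tuple(F2_CODES[s] for s in sorted(sums)))
    return legal


def simulate_cross(
    design: CrossDesign,
    true_map: TrueMap,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Simulate a full family: meiosis, zygotic selection, then genotyping noise.

    Offspring are formed from two independent gametes.  With a viability
    locus, each zygote survives with the fitness of its class there;
    rejection sampling continues until ``design.n_offspring`` survivors
    exist.  Calls are then corrupted (a random *legal* wrong code) at
    ``error_rate`` and masked to "U" at ``missing_rate``.  The truth record
    keeps crossover counts, the haplotype origin of each gamete at the
    viability locus (or at 0 on LG1 if none), and the pre-noise calls.
    """
    rng = np.random.default_rng(design.seed)
    n_markers = len(true_map.markers)
    parent_ids = list(design.parents)
    if design.design == "F2_SELF":
        parent_ids = [parent_ids[0], parent_ids[0]]

    vloc = true_map.viability_locus
    if vloc is not None:
        fit = {c: float(vloc.fitness.get(c, 1.0)) for c in ("AA", "AB", "BB")}
        if max(fit.values()) == 0.0:
            raise ConfigurationError("all fitness values are 0: impossible design")

    geno_rows, truth_rows, origin_rows = [], [], []
    attempts = 0
    while len(geno_rows) < design.n_offspring:
        attempts += 1
        if attempts > 1000 * design.n_offspring + 1000:
            raise ConfigurationError("viability selection rejects nearly all zygotes")
        g1, e1 = simulate_gamete(design.parents[parent_ids[0]], true_map, parent_ids[0], rng)
        g2, e2 = simulate_gamete(design.parents[parent_ids[1]], true_map, parent_ids[1], rng)
        probe_lg, probe_pos = (vloc.lg, vloc.position) if vloc is not None else (
            true_map.linkage_groups[0][0], 0.0)
        o1 = _origin_at(e1, probe_lg, probe_pos)
        o2 = _origin_at(e2, probe_lg, probe_pos)
        if vloc is not None:
            cls = ("AA", "AB", "BB")[o1 + o2]
            if rng.random() >= fit[cls]:
                continue
        geno_rows.append(g1 + g2)
        origin_rows.append((o1, o2))
        truth_rows.append(
            (sum(len(b) for _h, b in e1.values()), sum(len(b) for _h, b in e2.values()))
        )

    genos = np.array(geno_rows).T  # markers x individuals
    codes = np.array(F2_CODES, dtype=object)[genos]
    seg = _seg_types(design, n_markers)
    legal = _legal_codes(design, n_markers)
    true_codes = codes.copy()

    if error_rate > 0:
        err = rng.random(codes.shape) < error_rate
        for i, j in zip(*np.nonzero(err)):
            options = [c for c in legal[i] if c != codes[i, j]]
            if options:
                codes[i, j] = options[int(rng.integers(len(options)))]
    if missing_rate > 0:
        codes[rng.random(codes.shape) < missing_rate] = MISSING

    ind_ids = [f"ind{k + 1:04d}" for k in range(design.n_offspring)]
    mk = true_map.markers.set_index("marker")
    meta = pd.DataFrame(
        {
            "lg": mk["lg"],
            "position": mk["position"],
            "contig": mk["contig"],
            "seg_type": seg,
        }
    )
    calls = pd.DataFrame(codes, index=meta.index, columns=ind_ids)
    truth = {
        "crossovers": np.array(truth_rows),  # (n_offspring, 2 gametes)
        "viability_origins": np.array(origin_rows),  # haplotype origin per gamete
        "true_calls": pd.DataFrame(true_codes, index=meta.index, columns=ind_ids),
        "n_zygotes_drawn": attempts,
    }
    pop = "F2" if design.design == "F2_SELF" else "CP"
    return GenotypeMatrix(pop, calls, meta, truth)


# ---------------------------------------------------------------------------
# serialization

def write_genotypes(gm: GenotypeMatrix, path, dialect: str = "tsv") -> None:
    """Write a genotype matrix as TSV or a JoinMap-style ``.loc`` file."""
    if dialect == "tsv":
        with open(path, "w") as fh:
            fh.write(_to_tsv(gm))
    elif dialect == "joinmap_loc":
        with open(path, "w") as fh:
            fh.write(_to_loc(gm))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _to_tsv(gm: GenotypeMatrix) -> str:
    out = gm.markers.copy()
    table = pd.concat([out, gm.calls], axis=1)
    table.insert(0, "marker", table.index)
    buf = _io.StringIO()
    buf.write(f"#population_type={gm.population_type}\n")
    table.to_csv(buf, sep="\t", index=False, float_format="%.6g")
    return buf.getvalue()


_LOC_CODE = {
    "1:2:1": {"A": "a", "H": "h", "B": "b", MISSING: "-"},
    "1:1-mat": {"A": "ll", "H": "lm", "B": "lm", MISSING: "--"},
    "1:1-pat": {"A": "nn", "H": "np", "B": "np", MISSING: "--"},
}
_LOC_SEG = {"1:2:1": "<hkxhk>", "1:1-mat": "<lmxll>", "1:1-pat": "<nnxnp>"}


def _to_loc(gm: GenotypeMatrix, name: str = "meiomap") -> str:
    informative = gm.markers.index[gm.markers["seg_type"] != "uninf"]
    lines = [
        f"name = {name}",
        f"popt = {gm.population_type}",
        f"nloc = {len(informative)}",
        f"nind = {gm.n_offspring}",
        "",
    ]
    for m in informative:
        st = gm.markers.loc[m, "seg_type"]
        codes = [_LOC_CODE[st][c] for c in gm.calls.loc[m]]
        if gm.population_type == "CP":
            lines.append(f"{m} {_LOC_SEG[st]}\t" + " ".join(codes))
        else:
            lines.append(f"{m}\t" + " ".join(codes))
    return "\n".join(lines) + "\n"


def read_genotypes(path) -> GenotypeMatrix:
    """Read the TSV dialect written by :func:`write_genotypes`."""
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#population_type="):
            raise ValueError(f"{path}: line 1: missing #population_type header")
        pop = first.split("=", 1)[1]
        table = pd.read_csv(fh, sep="\t", dtype={"marker": str})
    meta_cols = ["marker", "lg", "position", "contig", "seg_type"]
    for col in meta_cols:
        if col not in table.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    table = table.set_index("marker")
    meta = table[meta_cols[1:]]
    calls = table.drop(columns=meta_cols[1:]).astype(str)
    legal = set(F2_CODES) | {MISSING}
    bad = ~calls.isin(legal)
    if bad.to_numpy().any():
        m = calls.index[bad.any(axis=1)][0]
        line_no = list(calls.index).index(m) + 3  # header comment + column row
        raise ValueError(f"{path}: line {line_no}: illegal call code at marker {m}")
    if table.index.duplicated().any():
        dup = table.index[table.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate marker id {dup!r}")
    return GenotypeMatrix(pop, calls, meta.copy())
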
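"""Evolutionary conservation of network hubs.

Per-residue conservation is the fraction of homologous sequences in a
cluster (UniRef50-style, supplied as an alignment with a designated seed)
that conserve the seed residue at that position. Hub degrees are reduced to
one value per residue — the maximum degree the residue reaches in any
simulated state — averaged per degree, and regressed against degree with
normality and constant-variance pre-tests. Pairwise global identities
between seed proteins come from a Needleman–Wunsch affine-gap alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from Bio import Align
from Bio.Align import substitution_matrices
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan

from . import chemistry
from .io import MSA
from .psn import HubRecord


@dataclass
class ConservationProfile:
    """Seed-residue conservation ratios within a homolog cluster.

    ``ratios`` maps the 1-based *ungapped* seed residue index to the
    fraction of non-seed cluster sequences conserving that residue; the
    seed itself is excluded from numerator and denominator.
    """

    ratios: dict[int, float]
    cluster_size: int
    mode: str
    seed_residues: dict[int, str]

    def __post_init__(self) -> None:
        for pos, r in self.ratios.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"ratio at position {pos} outside [0, 1]")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tresidue\tconservation\n")
            for pos in sorted(self.ratios):
                fh.write(f"{pos}\t{self.seed_residues[pos]}\t"
                         f"{self.ratios[pos]:.4f}\n")


@dataclass(frozen=True)
class DegreeConservationPoint:
    protein: str
    degree: int
    mean_conservation: float
    n_residues: int


@dataclass
class RegressionReport:
    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float
    shapiro_p: float
    variance_p: float
    normality_pass: bool
    constant_variance_pass: bool
    n_points: int
    variance_test: str

    def to_dict(self) -> dict:
        return {
            "slope": self.slope, "intercept": self.intercept,
            "r_squared": self.r_squared, "slope_stderr": self.slope_stderr,
            "shapiro_p": self.shapiro_p, "variance_p": self.variance_p,
            "normality_pass": self.normality_pass,
            "constant_variance_pass": self.constant_variance_pass,
            "n_points": self.n_points, "variance_test": self.variance_test,
        }


@dataclass
class AlignmentResult:
    seq_a: str
    seq_b: str
    aligned_a: str
    aligned_b: str
    score: float
    alignment_length: int
    identical: int

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.identical / self.alignment_length


def conservation_profile(msa: MSA, mode: str = "identity"
                         ) -> ConservationProfile:
    """Per-ungapped-seed-position conservation ratio in the cluster.

    ``mode="identity"`` counts exact residue matches; ``"similarity-groups"``
    additionally accepts residues in the same Clustal strong group. Gaps
    never match. The denominator is the number of non-seed sequences.
    """
    if mode not in ("identity", "similarity-groups"):
        raise ValueError(f"unknown conservation mode {mode!r}")
    others = [seq for ident, seq in msa.sequences if ident != msa.seed_id]
    if not others:
        raise ValueError("cluster needs at least one non-seed sequence")
    seed = msa.seed_sequence
    ratios: dict[int, float] = {}
    seed_res: dict[int, str] = {}
    for pos, col in enumerate(msa.seed_columns(), start=1):
        ref = seed[col]
        count = 0
        for seq in others:
            ch = seq[col]
            if ch == "-":
                continue
            if ch == ref or (mode == "similarity-groups"
                             and chemistry.same_strong_group(ch, ref)):
                count += 1
        ratios[pos] = count / len(others)
        seed_res[pos] = ref
    return ConservationProfile(ratios, cluster_size=len(others), mode=mode,
                               seed_residues=seed_res)


def max_degree_per_residue(hub_tables: list[list[HubRecord]]
                           ) -> dict[str, int]:
    """Across the simulated states of one protein, the highest hub degree
    each residue reaches — one occurrence per residue, at its maximum."""
    if not hub_tables:
        raise ValueError("need at least one state hub table")
    best: dict[str, int] = {}
    for table in hub_tables:
        for h in table:
            best[h.node] = max(best.get(h.node, 0), h.degree)
    return best


def degree_conservation_points(degree_map: dict[str, int],
                               profile: ConservationProfile,
                               protein: str,
                               position_of=None
                               ) -> list[DegreeConservationPoint]:
    """Group residues by their (maximum) hub degree and average their
    conservation ratios. ``position_of`` maps a hub node label to the
    1-based seed position; the default parses trailing digits of labels
    like ``A:E85``. A hub absent from the profile raises ``KeyError``."""
    if position_of is None:
        def position_of(label: str) -> int:
            digits = ""
            for ch in reversed(label):
                if ch.isdigit():
                    digits = ch + digits
                else:
                    break
            if not digits:
                raise ValueError(f"cannot parse residue index from {label!r}")
            return int(digits)
    grouped: dict[int, list[float]] = {}
    for node, degree in degree_map.items():
        pos = position_of(node)
        if pos not in profile.ratios:
            raise KeyError(f"hub residue {node!r} (position {pos}) missing "
                           "from the conservation profile")
        grouped.setdefault(degree, []).append(profile.ratios[pos])
    return [DegreeConservationPoint(protein, d, float(np.mean(v)), len(v))
            for d, v in sorted(grouped.items())]


def degree_regression(points: list[DegreeConservationPoint],
                      variance_test: str = "breusch-pagan",
                      alpha: float = 0.05) -> RegressionReport:
    """OLS of mean conservation on hub degree, pooled across proteins.

    Residuals are pre-tested for normality (Shapiro–Wilk) and constant
    variance (Breusch–Pagan, or Levene on a fitted-value median split);
    flags compare the p-values against ``alpha``.
    """
    if len(points) < 3:
        raise ValueError("regression needs at least 3 points")
    x = np.array([p.degree for p in points], dtype=float)
    y = np.array([p.mean_conservation for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("all degrees identical; regression undefined")
    design = sm.add_constant(x)
    fit = sm.OLS(y, design).fit()
    resid = np.asarray(fit.resid)
    # exactly collinear data: Shapiro on (numerically) zero residuals is
    # meaningless; report p=1 and a pass
    if np.allclose(resid, 0.0, atol=1e-12):
        shapiro_p = 1.0
        variance_p = 1.0
    else:
        shapiro_p = float(stats.shapiro(resid).pvalue)
        if variance_test == "breusch-pagan":
            variance_p = float(het_breuschpagan(resid, design)[1])
        elif variance_test == "levene":
            med = np.median(fit.fittedvalues)
            lo = resid[fit.fittedvalues <= med]
            hi = resid[fit.fittedvalues > med]
            if min(lo.size, hi.size) < 2:
                variance_p = 1.0
            else:
                variance_p = float(stats.levene(lo, hi).pvalue)
        else:
            raise ValueError(f"unknown variance test {variance_test!r}")
    return RegressionReport(
        slope=float(fit.params[1]), intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared), slope_stderr=float(fit.bse[1]),
        shapiro_p=shapiro_p, variance_p=variance_p,
        normality_pass=shapiro_p > alpha,
        constant_variance_pass=variance_p > alpha,
        n_points=len(points), variance_test=variance_test)


def needleman_wunsch(seq_a: str, seq_b: str, matrix: str = "BLOSUM62",
                     gap_open: float = 10.0, gap_extend: float = 0.5
                     ) -> AlignmentResult:
    """Optimal global alignment with affine gaps.

    A gap of length L costs ``gap_open + gap_extend * (L - 1)``. Percent
    identity is identical columns over the alignment length. With several
    co-optimal alignments the aligner's first (deterministic) one is
    reported; the score is shared by all of them.
    """
    for name, seq in (("A", seq_a), ("B", seq_b)):
        if not seq:
            raise ValueError(f"sequence {name} is empty")
        for i, ch in enumerate(seq):
            if ch.upper() not in chemistry.AMINO_ACIDS:
                raise ValueError(f"sequence {name}: non-amino-acid character "
                                 f"{ch!r} at position {i + 1}")
    if gap_open < 0 or gap_extend < 0:
        raise ValueError("gap penalties must be non-negative")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    alignments = aligner.align(seq_a, seq_b)
    best = alignments[0]
    a_line, b_line = str(best[0]), str(best[1])
    identical = sum(1 for x, y in zip(a_line, b_line) if x == y and x != "-")
    return AlignmentResult(seq_a, seq_b, a_line, b_line,
                           score=float(best.score),
                           alignment_length=len(a_line),
                           identical=identical)


def cross_protein_hub_alignment(msa: MSA, hub_degree_maps: dict[str, dict[str, int]],
                                min_degree: int = 5,
                                position_parsers: dict | None = None
                                ) -> list[dict]:
    """Classify alignment columns that are hubs in *all* proteins.

    ``msa`` aligns the seed proteins themselves (identifiers must match the
    keys of ``hub_degree_maps``, each mapping node label -> max degree).
    For every column where each protein contributes a hub of degree ≥
    ``min_degree``, the column is classed ``identical`` (one residue type),
    ``conserved`` (all within one Clustal strong group) or
    ``not-conserved``.
    """
    seqs = dict(msa.sequences)
    for prot in hub_degree_maps:
        if prot not in seqs:
            raise KeyError(f"protein {prot!r} not in alignment")

    def default_parser(label: str) -> int:
        digits = ""
        for ch in reversed(label):
            if ch.isdigit():
                digits = ch + digits
            else:
                break
        return int(digits)

    # per protein: ungapped position -> alignment column
    col_of: dict[str, dict[int, int]] = {}
    for prot in hub_degree_maps:
        seq = seqs[prot]
        col_of[prot] = {i + 1: c
                        for i, c in enumerate(c for c, ch in enumerate(seq)
                                              if ch != "-")}
    # per protein: alignment column -> degree (hubs only, >= min_degree)
    hub_cols: dict[str, dict[int, int]] = {}
    for prot, dmap in hub_degree_maps.items():
        parser = (position_parsers or {}).get(prot, default_parser)
        cols: dict[int, int] = {}
        for node, degree in dmap.items():
            if degree < min_degree:
                continue
            pos = parser(node)
            if pos not in col_of[prot]:
                raise KeyError(f"hub residue {node!r} of {prot!r} falls "
                               "outside the alignment")
            cols[col_of[prot][pos]] = degree
        hub_cols[prot] = cols

    common = set.intersection(*(set(c) for c in hub_cols.values()))
    out: list[dict] = []
    for col in sorted(common):
        residues = {prot: seqs[prot][col] for prot in hub_cols}
        aas = list(residues.values())
        if len(set(aas)) == 1:
            cls = "identical"
        elif any(all(a in g for a in aas)
                 for g in chemistry.CLUSTAL_STRONG_GROUPS):
            cls = "conserved"
        else:
            cls = "not-conserved"
        out.append({"column": col, "residues": residues,
                    "degrees": {p: hub_cols[p][col] for p in hub_cols},
                    "class": cls})
    return out
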
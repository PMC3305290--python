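"""Motif-content statistics: RSS permutation nulls, family tests, positions.

Three analyses probe what a motif catalog says about its source hairpins:

* **Notation content vs. randomly selected sequences (RSS).**  Each real
  motif is paired, per replicate, with a window drawn uniformly from a
  random training ss-string and masked to the motif's defined-character
  layout, so the null set shares the length multiset and per-motif masks of
  the observed set.  Empirical one-sided p-values with add-one smoothing,
  (r+1)/(n+1), are reported in both directions for each notation statistic.

* **Family-shared motifs.**  The number of catalog motifs present in every
  member of a precursor family, compared with equally sized random subsets
  of the precursor corpus.

* **Position profiles.**  Motif start positions anchored at the mature-arm
  5' end and scaled to the mean mature-arm span:  x' = (x - mir_start) * d_bar / d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import count_matrix
from .discovery import MotifCatalog, SSMotif
from .hairpins import Hairpin, SSString
from .alphabet import SSSymbol

__all__ = [
    "NotationSummary",
    "RSSResult",
    "PositionProfile",
    "summarize_notations",
    "sample_rss",
    "rss_pvalues",
    "family_common_motifs",
    "FamilyTestResult",
    "family_similarity_test",
    "normalized_positions",
    "plot_position_profile",
]

STAT_KEYS = ("A", "C", "G", "U", "L", "D", "R", "combined", "up_neighbour", "down_neighbour")


@dataclass
class NotationSummary:
    """Defined-notation counts over a set of motifs (wildcards never counted).

    ``combined`` counts positions carrying both a nucleotide and a structure
    notation (e.g. ``A_L``); ``up_neighbour`` counts defined structure
    notations immediately 5' of a defined nucleotide (``N_L A_S``);
    ``down_neighbour`` the 3' analogue (``A_S N_L``).
    """

    A: int = 0
    C: int = 0
    G: int = 0
    U: int = 0
    L: int = 0
    D: int = 0
    R: int = 0
    combined: int = 0
    up_neighbour: int = 0
    down_neighbour: int = 0

    def as_dict(self) -> dict[str, int]:
        return {k: getattr(self, k) for k in STAT_KEYS}

    @property
    def total_defined(self) -> int:
        return self.A + self.C + self.G + self.U + self.L + self.D + self.R


def summarize_notations(motifs: list[SSMotif]) -> NotationSummary:
    """Count defined notations, combined positions and structure neighbours."""
    out = NotationSummary()
    for motif in motifs:
        symbols = motif.symbols if isinstance(motif, SSMotif) else tuple(motif)
        for i, sym in enumerate(symbols):
            if sym.nuc != "N":
                setattr(out, sym.nuc, getattr(out, sym.nuc) + 1)
            if sym.struct != "S":
                setattr(out, sym.struct, getattr(out, sym.struct) + 1)
            if sym.nuc != "N" and sym.struct != "S":
                out.combined += 1
            if i + 1 < len(symbols):
                nxt = symbols[i + 1]
                if sym.struct != "S" and nxt.nuc != "N":
                    out.up_neighbour += 1
                if sym.nuc != "N" and nxt.struct != "S":
                    out.down_neighbour += 1
    return out


def sample_rss(
    motifs: list[SSMotif],
    training_ss: list[SSString],
    rng: np.random.Generator,
    mask_mode: str = "exact",
) -> list[SSMotif]:
    """One null replicate: a masked random window per motif.

    For each motif a training string and a window of the motif's length are
    drawn uniformly; the window keeps its nucleotide character exactly where
    the motif defines one (else N) and likewise for structure.  The sampled
    set therefore reproduces the length multiset and defined-character masks
    of the real motifs.

    With ``mask_mode="exact"`` (the normative default) each motif's mask is
    applied position for position; statistics that depend only on the mask
    layout (combined positions, structure neighbours) are then invariant
    under the null.  ``mask_mode="shuffled"`` instead permutes the mask
    positions within each motif, preserving the per-motif counts of defined
    nucleotide and structure notations while randomizing their arrangement,
    which gives those layout statistics a nondegenerate null.
    """
    if not training_ss:
        raise ValueError("empty training set")
    if mask_mode not in ("exact", "shuffled"):
        raise ValueError(f"unknown mask_mode {mask_mode!r}")
    lens = np.array([len(s) for s in training_ss])
    out = []
    for motif in motifs:
        m = len(motif)
        eligible = np.nonzero(lens >= m)[0]
        if len(eligible) == 0:
            raise ValueError(f"motif {motif.human} is longer than every training string")
        s_idx = int(eligible[rng.integers(len(eligible))])
        ss = training_ss[s_idx]
        start = int(rng.integers(len(ss) - m + 1))
        mask = [(sym.nuc != "N", sym.struct != "S") for sym in motif.symbols]
        if mask_mode == "shuffled":
            mask = [mask[j] for j in rng.permutation(m)]
        symbols = []
        for j, (nuc_def, struct_def) in enumerate(mask):
            nuc = "ACGUN"[ss.nuc[start + j]] if nuc_def else "N"
            struct = "LDRS"[ss.struct[start + j]] if struct_def else "S"
            symbols.append(SSSymbol(nuc, struct))
        masked = SSMotif(tuple(symbols))
        # mask/length conservation, by construction
        assert len(masked) == m
        assert sorted(
            ((s.nuc != "N"), (s.struct != "S")) for s in masked.symbols
        ) == sorted(((s.nuc != "N"), (s.struct != "S")) for s in motif.symbols)
        out.append(masked)
    return out


@dataclass
class RSSResult:
    """Observed notation counts against the RSS null."""

    observed: NotationSummary
    null_mean: dict[str, float]
    null_sd: dict[str, float]
    p_enriched: dict[str, float]
    p_depleted: dict[str, float]
    n_reps: int

    def to_dataframe(self) -> pd.DataFrame:
        obs = self.observed.as_dict()
        return pd.DataFrame(
            {
                "statistic": list(STAT_KEYS),
                "observed": [obs[k] for k in STAT_KEYS],
                "null_mean": [self.null_mean[k] for k in STAT_KEYS],
                "null_sd": [self.null_sd[k] for k in STAT_KEYS],
                "p_enriched": [self.p_enriched[k] for k in STAT_KEYS],
                "p_depleted": [self.p_depleted[k] for k in STAT_KEYS],
            }
        )


def rss_pvalues(
    motifs: list[SSMotif],
    training_ss: list[SSString],
    n_reps: int = 10_000,
    seed: int | np.random.Generator = 0,
    mask_mode: str = "exact",
) -> RSSResult:
    """Empirical enrichment/depletion p-values of motif notation content.

    p_enriched = (#{replicates with null >= observed} + 1) / (n_reps + 1);
    p_depleted analogously with <=.  Reproducible given the seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = summarize_notations(motifs)
    obs = observed.as_dict()
    null = {k: np.empty(n_reps) for k in STAT_KEYS}
    for rep in range(n_reps):
        summary = summarize_notations(
            sample_rss(motifs, training_ss, rng, mask_mode=mask_mode)
        ).as_dict()
        for k in STAT_KEYS:
            null[k][rep] = summary[k]
    p_enriched = {k: float((np.sum(null[k] >= obs[k]) + 1) / (n_reps + 1)) for k in STAT_KEYS}
    p_depleted = {k: float((np.sum(null[k] <= obs[k]) + 1) / (n_reps + 1)) for k in STAT_KEYS}
    return RSSResult(
        observed=observed,
        null_mean={k: float(null[k].mean()) for k in STAT_KEYS},
        null_sd={k: float(null[k].std(ddof=0)) for k in STAT_KEYS},
        p_enriched=p_enriched,
        p_depleted=p_depleted,
        n_reps=n_reps,
    )


def family_common_motifs(member_ss: list[SSString], catalog: MotifCatalog) -> int:
    """Number of catalog motifs occurring in every family member."""
    if len(member_ss) < 2:
        raise ValueError("a family needs at least 2 members")
    presence = count_matrix(catalog.motifs, member_ss, mode="binary")
    return int(presence.all(axis=0).sum())


@dataclass
class FamilyTestResult:
    observed_common: int
    p_value: float
    null_common: np.ndarray
    n_reps: int


def family_similarity_test(
    family_ss: list[SSString],
    all_ss: list[SSString],
    catalog: MotifCatalog,
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> FamilyTestResult:
    """Are family members richer in shared motifs than random precursor sets?

    p = (#{random same-size subsets with common-motif count >= observed} + 1)
        / (n_reps + 1).
    """
    fam_size = len(family_ss)
    if fam_size > len(all_ss):
        raise ValueError("family size exceeds corpus size")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = family_common_motifs(family_ss, catalog)
    presence = count_matrix(catalog.motifs, all_ss, mode="binary") > 0  # (n_seq, k)
    null = np.empty(n_reps, dtype=np.int64)
    for rep in range(n_reps):
        subset = rng.choice(len(all_ss), size=fam_size, replace=False)
        null[rep] = int(presence[subset].all(axis=0).sum())
    p = float((np.sum(null >= observed) + 1) / (n_reps + 1))
    return FamilyTestResult(observed_common=observed, p_value=p, null_common=null, n_reps=n_reps)


@dataclass
class PositionProfile:
    """Pooled normalized start positions of one motif over annotated hairpins."""

    motif_text: str
    positions: list[float]
    d_bar: float
    n_hairpins_used: int
    n_skipped: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"motif": self.motif_text, "x_prime": self.positions})


def normalized_positions(
    motif: SSMotif,
    hairpins: list[Hairpin],
    d_bar: float | str = "auto",
) -> PositionProfile:
    """Motif start positions anchored at mir_start and length-normalized.

    For an occurrence starting at x on a hairpin whose mature-arm span is
    d = mir_end - mir_start:  x' = (x - mir_start) * d_bar / d, with d_bar
    the mean span over the supplied annotated set when "auto".  x' = 0 iff
    the motif starts exactly at mir_start.  Hairpins without an annotation
    are skipped with a warning.
    """
    from .discovery import occurrences

    annotated = [hp for hp in hairpins if hp.mature is not None]
    n_skipped = len(hairpins) - len(annotated)
    if n_skipped:
        warnings.warn(f"{n_skipped} hairpin(s) lack mature annotations; skipped", stacklevel=2)
    if not annotated:
        raise ValueError("no annotated hairpins supplied")
    spans = [hp.mature.mir_end - hp.mature.mir_start for hp in annotated]
    if any(d <= 0 for d in spans):
        raise ValueError("mature-arm span must be positive")
    d_bar_value = float(np.mean(spans)) if d_bar == "auto" else float(d_bar)
    positions: list[float] = []
    for hp, d in zip(annotated, spans):
        ss = hp.encode()
        for x in occurrences(motif, ss):
            positions.append((x - hp.mature.mir_start) * d_bar_value / d)
    return PositionProfile(
        motif_text=motif.human,
        positions=positions,
        d_bar=d_bar_value,
        n_hairpins_used=len(annotated),
        n_skipped=n_skipped,
    )


def plot_position_profile(profile: PositionProfile, path, bins: int = 40) -> None:
    """Histogram of normalized motif positions (one motif per figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.hist(profile.positions, bins=bins, color="firebrick")
    ax.axvline(0.0, color="black", lw=0.8, ls="--")
    ax.set_xlabel("normalized position x' (0 = mature 5' end)")
    ax.set_ylabel("occurrences")
    ax.set_title(profile.motif_text)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
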
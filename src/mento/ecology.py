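"""Comparative nutritional ecology over predicted minimal environments.

Given per-organism MINENV sets and an organism-by-environment presence
table, these routines quantify how nutritional requirements track
ecological co-occurrence: Jaccard similarity in nutrient space vs.
environment space, binned similarity curves, split-half distances between
aggregate (union) MINENVs inside vs. outside an environment, in-silico
growth of held-out organisms on aggregate media, a model-free containment
variant for curated media catalogues, and rank correlations between MINENV
size (fastidiousness) and arbitrary organism covariates.

All resampling is driven by an explicit integer seed through one
numpy Generator per call, so every analysis is bit-reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PreconditionError, UnknownIdentifierError
from .fba_core import DEFAULT_CUTOFF, DEFAULT_UPTAKE_MAGNITUDE, Medium, grows

__all__ = [
    "EcologicalProfile",
    "SimilarityCurve",
    "SplitHalfResult",
    "AggregateGrowthResult",
    "ContainmentResult",
    "jaccard",
    "aggregate_minenv",
    "binned_similarity_curve",
    "split_half_environment_distance",
    "growth_on_aggregate",
    "containment_test",
    "fastidiousness_correlates",
    "mean_pair_score",
    "read_profile",
    "write_profile",
    "read_minenv_table",
    "read_covariate",
    "read_pair_scores",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class EcologicalProfile:
    """Binary organism-by-environment presence matrix."""

    organisms: list[str]
    environments: list[str]
    presence: np.ndarray  # bool, organisms x environments

    def __post_init__(self):
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.organisms), len(self.environments)):
            raise PreconditionError(
                "presence matrix shape does not match organism/environment lists"
            )
        empty = [o for o, row in zip(self.organisms, self.presence) if not row.any()]
        if empty:
            raise PreconditionError(
                f"organisms present in no environment: {empty}"
            )

    def environments_of(self, org: str) -> frozenset[str]:
        try:
            i = self.organisms.index(org)
        except ValueError:
            raise UnknownIdentifierError(f"unknown organism {org!r}") from None
        return frozenset(
            e for e, p in zip(self.environments, self.presence[i]) if p
        )

    def members_of(self, env: str) -> list[str]:
        try:
            j = self.environments.index(env)
        except ValueError:
            raise UnknownIdentifierError(f"unknown environment {env!r}") from None
        return [o for o, p in zip(self.organisms, self.presence[:, j]) if p]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.presence.astype(int),
            index=pd.Index(self.organisms, name="organism"),
            columns=self.environments,
        )


@dataclass
class SimilarityCurve:
    """Binned fraction of organism pairs above MINENV-similarity thresholds.

    ``ratio[b, t]`` is the fraction of pairs in ecological-distance bin
    ``b`` whose MINENV similarity (percent Jaccard) reaches threshold
    ``t``; bins holding fewer than the pair-count floor are flagged and
    excluded from the per-threshold Spearman correlation, which relates
    bin ecological *similarity* (1 - distance) to the ratio, so positive
    rho means co-distributed organisms eat alike.
    """

    bin_edges: np.ndarray
    thresholds: tuple[float, ...]
    ratio: np.ndarray  # bins x thresholds, NaN for empty bins
    pair_counts: np.ndarray
    flagged: np.ndarray  # bins with < min_pairs_per_bin
    spearman: dict[float, tuple[float, float] | None]


@dataclass
class SplitHalfResult:
    within_mean: float
    within_sd: float
    random_mean: float
    random_sd: float
    per_trial: pd.DataFrame


@dataclass
class AggregateGrowthResult:
    inside_growth_fraction: float
    outside_growth_fraction: float
    per_trial: pd.DataFrame


@dataclass
class ContainmentResult:
    inside_fraction: float
    outside_fraction: float
    per_trial: pd.DataFrame


# ---------------------------------------------------------------------------
# set similarity


def jaccard(s1, s2) -> float:
    """|intersection| / |union|; two empty sets count as identical (1)."""
    s1, s2 = set(s1), set(s2)
    if not s1 and not s2:
        return 1.0
    return len(s1 & s2) / len(s1 | s2)


def aggregate_minenv(minenvs) -> frozenset[str]:
    """Union of MINENVs — the shared nutrient pool of a group."""
    minenvs = list(minenvs)
    if not minenvs:
        raise PreconditionError("aggregate of an empty group is undefined")
    out: set[str] = set()
    for s in minenvs:
        out |= set(s)
    return frozenset(out)


# ---------------------------------------------------------------------------
# binned similarity curve


def binned_similarity_curve(
    minenvs: dict[str, frozenset],
    profile: EcologicalProfile,
    n_bins: int = 20,
    thresholds=(30.0, 50.0, 70.0),
    min_pairs_per_bin: int = 1000,
) -> SimilarityCurve:
    """Fraction of organism pairs with similar MINENVs, by ecological distance.

    For every unordered pair of organisms shared between ``minenvs`` and the
    profile, computes ecological distance (1 - Jaccard of environment sets)
    and MINENV similarity (100 x Jaccard of nutrient sets), bins pairs into
    ``n_bins`` equal-width distance bins on [0, 1], and per bin reports the
    fraction of pairs at or above each similarity threshold.
    """
    orgs = sorted(set(minenvs) & set(profile.organisms))
    if len(orgs) < 2:
        raise PreconditionError(
            "need at least 2 organisms shared between MINENVs and profile"
        )
    env_sets = {o: profile.environments_of(o) for o in orgs}
    dists, sims = [], []
    for a, b in itertools.combinations(orgs, 2):
        dists.append(1.0 - jaccard(env_sets[a], env_sets[b]))
        sims.append(100.0 * jaccard(minenvs[a], minenvs[b]))
    dists = np.asarray(dists)
    sims = np.asarray(sims)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(dists, edges[1:-1]), 0, n_bins - 1)
    thresholds = tuple(float(t) for t in thresholds)
    ratio = np.full((n_bins, len(thresholds)), np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        mask = which == b
        counts[b] = int(mask.sum())
        if counts[b]:
            for t, thr in enumerate(thresholds):
                ratio[b, t] = float(np.mean(sims[mask] >= thr))
    flagged = counts < min_pairs_per_bin
    centers = (edges[:-1] + edges[1:]) / 2
    spearman: dict[float, tuple[float, float] | None] = {}
    for t, thr in enumerate(thresholds):
        ok = (~flagged) & (counts > 0)
        if ok.sum() < 2:
            spearman[thr] = None
            continue
        eco_sim = 1.0 - centers[ok]
        import warnings

        with warnings.catch_warnings():
            # a constant ratio column has no rank trend; report it as absent
            warnings.simplefilter("ignore")
            rho, p = stats.spearmanr(eco_sim, ratio[ok, t])
        spearman[thr] = None if np.isnan(rho) else (float(rho), float(p))
    return SimilarityCurve(
        bin_edges=edges,
        thresholds=thresholds,
        ratio=ratio,
        pair_counts=counts,
        flagged=flagged,
        spearman=spearman,
    )


# ---------------------------------------------------------------------------
# split-half aggregate distances


def _env_groups(minenvs, profile, environment, need):
    members = [o for o in profile.members_of(environment) if o in minenvs]
    non_members = [
        o
        for o in profile.organisms
        if o in minenvs and o not in set(profile.members_of(environment))
    ]
    if len(members) < need:
        raise PreconditionError(
            f"environment {environment!r} has {len(members)} organisms with "
            f"MINENVs; need >= {need}"
        )
    return members, non_members


def split_half_environment_distance(
    minenvs: dict[str, frozenset],
    profile: EcologicalProfile,
    environment: str,
    n_trials: int = 100,
    group_size: int | None = None,
    seed: int = 0,
) -> SplitHalfResult:
    """Distance between aggregate MINENVs of two halves of an environment.

    Per trial, two disjoint ``group_size`` subsets of the environment's
    members are drawn and the Jaccard distance between their aggregate
    MINENVs recorded; matched control trials draw both groups from strict
    non-members.  Co-habiting organisms sharing a nutrient pool show a
    smaller within-environment distance than the control.
    """
    members_all = [o for o in profile.members_of(environment) if o in minenvs]
    if group_size is None:
        group_size = len(members_all) // 2
    if group_size < 1:
        raise PreconditionError("group_size must be >= 1")
    members, non_members = _env_groups(minenvs, profile, environment, 2 * group_size)
    if len(non_members) < 2 * group_size:
        raise PreconditionError(
            f"environment {environment!r}: only {len(non_members)} non-members "
            f"available for the control; need >= {2 * group_size}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for trial in range(n_trials):
        pick = rng.choice(len(members), size=2 * group_size, replace=False)
        g1 = [members[i] for i in pick[:group_size]]
        g2 = [members[i] for i in pick[group_size:]]
        d_within = 1.0 - jaccard(
            aggregate_minenv(minenvs[o] for o in g1),
            aggregate_minenv(minenvs[o] for o in g2),
        )
        pick = rng.choice(len(non_members), size=2 * group_size, replace=False)
        r1 = [non_members[i] for i in pick[:group_size]]
        r2 = [non_members[i] for i in pick[group_size:]]
        d_random = 1.0 - jaccard(
            aggregate_minenv(minenvs[o] for o in r1),
            aggregate_minenv(minenvs[o] for o in r2),
        )
        rows.append(
            {"trial": trial, "within_distance": d_within, "random_distance": d_random}
        )
    per_trial = pd.DataFrame(rows)
    return SplitHalfResult(
        within_mean=float(per_trial.within_distance.mean()),
        within_sd=float(per_trial.within_distance.std(ddof=1)) if n_trials > 1 else 0.0,
        random_mean=float(per_trial.random_distance.mean()),
        random_sd=float(per_trial.random_distance.std(ddof=1)) if n_trials > 1 else 0.0,
        per_trial=per_trial,
    )


# ---------------------------------------------------------------------------
# growth on aggregate media


def _builder_split(rng, members, holdout_fraction):
    n = len(members)
    n_build = int(round((1.0 - holdout_fraction) * n))
    n_build = min(max(n_build, 1), n - 1)
    pick = rng.permutation(n)
    builders = [members[i] for i in pick[:n_build]]
    tested = [members[i] for i in pick[n_build:]]
    return builders, tested


def growth_on_aggregate(
    models: dict,
    minenvs: dict[str, frozenset],
    profile: EcologicalProfile,
    environment: str,
    holdout_fraction: float = 0.5,
    cutoff: float = DEFAULT_CUTOFF,
    n_trials: int = 10,
    seed: int = 0,
    uptake_magnitude: float = DEFAULT_UPTAKE_MAGNITUDE,
) -> AggregateGrowthResult:
    """FBA growth of held-out organisms on an environment's aggregate MINENV.

    Per trial the aggregate is the union of MINENVs of a random subset of
    the environment's members; the remaining members (never the builders)
    and an equal-size sample of strict non-members are then tested for
    growth on that aggregate medium.
    """
    if not 0 < holdout_fraction < 1:
        raise PreconditionError("holdout_fraction must be in (0, 1)")
    usable = set(models) & set(minenvs)
    members = [o for o in profile.members_of(environment) if o in usable]
    if len(members) < 2:
        raise PreconditionError(
            f"environment {environment!r} needs >= 2 members with models"
        )
    member_set = set(profile.members_of(environment))
    outsiders = [o for o in profile.organisms if o in models and o not in member_set]
    rng = np.random.default_rng(seed)
    rows = []
    for trial in range(n_trials):
        builders, tested = _builder_split(rng, members, holdout_fraction)
        aggregate = aggregate_minenv(minenvs[o] for o in builders)
        medium_pool = aggregate  # uptake restricted to the shared pool
        n_out = min(len(tested), len(outsiders))
        out_sample = (
            [outsiders[i] for i in rng.choice(len(outsiders), n_out, replace=False)]
            if n_out
            else []
        )
        for group, orgs in (("inside", tested), ("outside", out_sample)):
            for o in orgs:
                ok = grows(
                    models[o],
                    Medium(
                        medium_pool & set(models[o].exchange_metabolite_ids),
                        uptake_magnitude,
                    ),
                    cutoff,
                )
                rows.append({"trial": trial, "group": group, "organism": o, "grows": ok})
    per_trial = pd.DataFrame(rows)
    ins = per_trial[per_trial.group == "inside"].grows
    out = per_trial[per_trial.group == "outside"].grows
    return AggregateGrowthResult(
        inside_growth_fraction=float(ins.mean()) if len(ins) else float("nan"),
        outside_growth_fraction=float(out.mean()) if len(out) else float("nan"),
        per_trial=per_trial,
    )


def containment_test(
    media: dict[str, frozenset],
    profile: EcologicalProfile,
    environment: str,
    n_trials: int = 10,
    seed: int = 0,
    holdout_fraction: float = 0.5,
) -> ContainmentResult:
    """Model-free variant: growth means the organism's own medium is a
    subset of the aggregate built from co-members' media."""
    members = [o for o in profile.members_of(environment) if o in media]
    if len(members) < 2:
        raise PreconditionError(
            f"environment {environment!r} needs >= 2 members with media"
        )
    member_set = set(profile.members_of(environment))
    outsiders = [o for o in profile.organisms if o in media and o not in member_set]
    rng = np.random.default_rng(seed)
    rows = []
    for trial in range(n_trials):
        builders, tested = _builder_split(rng, members, holdout_fraction)
        aggregate = aggregate_minenv(media[o] for o in builders)
        n_out = min(len(tested), len(outsiders))
        out_sample = (
            [outsiders[i] for i in rng.choice(len(outsiders), n_out, replace=False)]
            if n_out
            else []
        )
        for group, orgs in (("inside", tested), ("outside", out_sample)):
            for o in orgs:
                rows.append(
                    {
                        "trial": trial,
                        "group": group,
                        "organism": o,
                        "grows": set(media[o]) <= set(aggregate),
                    }
                )
    per_trial = pd.DataFrame(rows)
    ins = per_trial[per_trial.group == "inside"].grows
    out = per_trial[per_trial.group == "outside"].grows
    return ContainmentResult(
        inside_fraction=float(ins.mean()) if len(ins) else float("nan"),
        outside_fraction=float(out.mean()) if len(out) else float("nan"),
        per_trial=per_trial,
    )


# ---------------------------------------------------------------------------
# covariate correlations


def fastidiousness_correlates(
    minenv_sizes: dict[str, float],
    covariate: dict[str, float],
    method: str = "spearman",
) -> tuple[float, float, int]:
    """Rank correlation between MINENV size and an organism covariate.

    Returns (rho, p, n) over the organisms shared by both maps; ties get
    average ranks (scipy's default).
    """
    if method != "spearman":
        raise PreconditionError(f"unsupported method {method!r}")
    shared = sorted(set(minenv_sizes) & set(covariate))
    if len(shared) < 3:
        raise PreconditionError(
            f"need >= 3 shared organisms, have {len(shared)}"
        )
    x = [minenv_sizes[o] for o in shared]
    y = [covariate[o] for o in shared]
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), len(shared)


def mean_pair_score(org: str, pair_scores: dict[tuple[str, str], float]) -> float:
    """Average of an organism's pairwise scores over all its pairings."""
    vals = [v for (a, b), v in pair_scores.items() if org in (a, b)]
    if not vals:
        raise UnknownIdentifierError(f"organism {org!r} appears in no pair")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# tabular I/O (TSV conventions shared with the CLI)


def read_profile(path) -> EcologicalProfile:
    """Organism x environment 0/1 TSV with a header row of environment ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty or not len(df.columns):
        raise PreconditionError(f"{path}: profile table is empty or lacks a header")
    return EcologicalProfile(
        organisms=[str(o) for o in df.index],
        environments=[str(e) for e in df.columns],
        presence=df.to_numpy(dtype=bool),
    )


def write_profile(profile: EcologicalProfile, path) -> None:
    profile.to_dataframe().to_csv(path, sep="\t")


def read_minenv_table(path) -> tuple[dict[str, int], dict[str, frozenset]]:
    """Read the TSV written by the core module's results table.

    Returns (sizes, minenv sets) keyed by organism id.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"organism", "minimal_size", "minenv"}
    if not required <= set(df.columns):
        raise PreconditionError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    sizes, sets_ = {}, {}
    for _, row in df.iterrows():
        org = row["organism"]
        sizes[org] = int(row["minimal_size"])
        sets_[org] = frozenset(x for x in row["minenv"].split(",") if x)
    return sizes, sets_


def read_covariate(path) -> dict[str, float]:
    """Two-column TSV: organism, value."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise PreconditionError(f"{path}: covariate table needs 2 columns")
    return {str(r.iloc[0]): float(r.iloc[1]) for _, r in df.iterrows()}


def read_pair_scores(path) -> dict[tuple[str, str], float]:
    """Three-column TSV: organism A, organism B, score."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise PreconditionError(f"{path}: pair-score table needs 3 columns")
    return {
        (str(r.iloc[0]), str(r.iloc[1])): float(r.iloc[2]) for _, r in df.iterrows()
    }
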
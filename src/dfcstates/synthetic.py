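"""Synthetic multi-subject cohorts with planted connectivity states.

The generator emulates the statistical structure the downstream analysis
assumes: K latent connectivity states with distinct correlation patterns
over the 53 ROIs, Markovian dwell at window resolution, subject-varying
occupancy coupled to behavioral scores through a latent trait, nested
site/family random effects, and an explicit exposure -> mediator ->
outcome path.  Every cohort carries a :class:`SyntheticTruth` record
sufficient to score recovery of each planted quantity.

Randomness is routed through one ``numpy.random.SeedSequence``; per-subject
streams are spawned children of the cohort seed, so a cohort is
byte-reproducible and individual subjects can be re-simulated in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io import BehaviorTable, ParcellationMeta, RoiTimecourse, load_parcellation

__all__ = [
    "StateSpec",
    "CohortSpec",
    "SyntheticTruth",
    "make_state_covariances",
    "simulate_state_sequence",
    "simulate_subject",
    "simulate_cohort",
]


class ParameterError(ValueError):
    """Infeasible generator parameters (e.g. dwell vs occupancy)."""


class ConstructionError(RuntimeError):
    """Positive-definite repair of a planted covariance failed."""


# Within-network target correlations for the segregated state.  Sensory
# networks (AUD, SM, VS) are the strongest, mirroring the canonical
# "strong sensory" reoccurring pattern in resting-state DFC.
_WITHIN = {"SC": 0.50, "AUD": 0.65, "SM": 0.65, "VS": 0.65,
           "CC": 0.40, "DM": 0.45, "CB": 0.50}
# Between-network blocks of the segregated state: negative sensorimotor-
# visual and visual-cerebellar coupling, weak positive elsewhere.
_BETWEEN = {("SM", "VS"): -0.45, ("VS", "CB"): -0.40, ("AUD", "SM"): 0.35,
            ("SC", "DM"): -0.30, ("CC", "CB"): 0.30}
_BETWEEN_DEFAULT = 0.05


@dataclass
class StateSpec:
    """K planted connectivity states and their temporal dynamics."""

    covariances: List[np.ndarray]
    dwell_mean_windows: float = 4.0
    base_occupancy: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.covariances = [np.asarray(c, dtype=float) for c in self.covariances]
        if self.K < 2:
            raise ParameterError("need at least 2 states")
        if self.base_occupancy is None:
            self.base_occupancy = default_base_occupancy(self.K)
        self.base_occupancy = np.asarray(self.base_occupancy, dtype=float)
        if len(self.base_occupancy) != self.K:
            raise ParameterError("base_occupancy length must equal K")
        if not np.isclose(self.base_occupancy.sum(), 1.0):
            raise ParameterError("base_occupancy must sum to 1")
        if self.dwell_mean_windows <= 1.0:
            raise ParameterError("dwell_mean_windows must exceed 1 window")

    @property
    def K(self) -> int:
        return len(self.covariances)

    @property
    def n_rois(self) -> int:
        return self.covariances[0].shape[0]


def default_base_occupancy(K: int) -> np.ndarray:
    """Default stationary occupancy: rare segregated state (first),
    dominant sparse state (last), remainder spread evenly.

    For K=5 this is (0.12, 0.1467, 0.1467, 0.1467, 0.44), inside the
    occupancy ranges reported for the corresponding states in children's
    resting-state DFC (segregated ~8-13%, sparse-dominant ~39-48%).
    """
    if K == 2:
        return np.array([0.3, 0.7])
    occ = np.full(K, (1.0 - 0.12 - 0.44) / (K - 2))
    occ[0] = 0.12
    occ[-1] = 0.44
    return occ


@dataclass
class CohortSpec:
    """Cohort-level design: sampling frame, effects and noise scales.

    ``occupancy_effect`` couples a latent N(0,1) subject trait to the
    log-odds of the segregated (first) vs sparse (last) state, moving
    occupancy mass strictly between those two states.
    ``assoc_effect_r`` is the target correlation between the trait-driven
    occupancy and each generic behavioral score (negative for cognitive
    scores, positive for psychiatric ones).  ``mediation`` gives the raw
    path coefficients on z-scored occupancy for the designated mediation
    triple (occupancy -> cbcl_attention -> nihtbx_fluid).
    """

    n_subjects: int = 200
    n_sites: int = 10
    families_per_site: int = 15
    scans_per_subject: int = 1
    T: int = 380
    tr_seconds: float = 0.8
    block_len_tr: int = 40
    occupancy_effect: float = 0.5
    assoc_effect_r: float = 0.08
    mediation: Dict[str, float] = field(
        default_factory=lambda: {"a": 0.3, "b": -0.3, "c_prime": -0.36})
    site_sd: float = 0.15
    family_sd: float = 0.20
    noise_sd: float = 0.15
    simulate_motion: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("site_sd", "family_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.T < self.block_len_tr:
            raise ParameterError("T must cover at least one state block")


@dataclass
class SyntheticTruth:
    """Ground truth planted in one synthetic cohort."""

    covariances: List[np.ndarray]
    base_occupancy: np.ndarray
    subject_ids: List[str]
    traits: np.ndarray                    # latent trait per subject
    expected_occupancy: np.ndarray        # n_subjects x K, trait-shifted pi
    realized_occupancy: np.ndarray        # n_subjects x K, TR fractions
    block_sequences: Dict[str, List[List[int]]]  # subject -> per-scan blocks
    assoc_effect_r: float
    score_couplings: Dict[str, float]     # score column -> planted sign*r
    mediation_paths: Dict[str, float]     # a, b, c_prime
    true_ab: float
    true_proportion_mediated: float
    seed: int

    def to_json(self, path) -> None:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            raise TypeError(type(x))
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, default=conv)


# ---------------------------------------------------------------------------
# planted covariances


def _block_matrix(parcellation: ParcellationMeta,
                  within: Dict[str, float],
                  between: Dict[Tuple[str, str], float],
                  between_default: float) -> np.ndarray:
    nets = parcellation.networks.to_numpy()
    R = parcellation.n_rois
    C = np.full((R, R), between_default)
    for (a, b), v in between.items():
        ia = nets == a
        ib = nets == b
        C[np.ix_(ia, ib)] = v
        C[np.ix_(ib, ia)] = v
    for net, v in within.items():
        im = nets == net
        C[np.ix_(im, im)] = v
    np.fill_diagonal(C, 1.0)
    return C


def nearest_correlation(C: np.ndarray, min_eig: float = 1e-4,
                        max_iter: int = 100) -> np.ndarray:
    """Repair a symmetric matrix to a positive-definite correlation matrix
    by alternating eigenvalue clipping with unit-diagonal restoration."""
    C = (C + C.T) / 2.0
    for _ in range(max_iter):
        w, V = np.linalg.eigh(C)
        if w.min() > min_eig and np.allclose(np.diag(C), 1.0, atol=1e-12):
            return C
        w = np.clip(w, min_eig, None)
        C = (V * w) @ V.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        np.fill_diagonal(C, 1.0)
    w = np.linalg.eigvalsh(C)
    if w.min() <= 1e-6:
        raise ConstructionError(
            f"positive-definite repair failed (min eig {w.min():.2e})")
    return C


def make_state_covariances(parcellation: Optional[ParcellationMeta] = None,
                           K: int = 5, seed: int = 0,
                           dwell_mean_windows: float = 4.0,
                           base_occupancy: Optional[Sequence[float]] = None,
                           ) -> StateSpec:
    """Construct K planted state correlation matrices over the parcellation.

    State 0 is the "segregated" pattern: strong positive within-network
    blocks with negative SM-VS and VS-CB coupling.  State K-1 is the
    "sparse" pattern: near-zero off-diagonal structure (a weak-amplitude
    block pattern rather than exact zeros, so the state is still a
    recoverable direction in connectivity space).  Every intermediate
    state carries its own seeded network-block signature — a distinct
    within-network profile plus a random subset of strong signed
    between-network blocks — so states are well-separated directions
    rather than collinear blends.  All matrices are repaired to
    positive-definite correlation form.
    """
    if parcellation is None:
        parcellation = load_parcellation()
    if K < 2:
        raise ParameterError("K must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0C0]))
    nets = list(_WITHIN)
    segregated = _block_matrix(parcellation, _WITHIN, _BETWEEN, _BETWEEN_DEFAULT)
    iu = np.triu_indices(parcellation.n_rois, 1)

    def signature_pattern() -> np.ndarray:
        """A state-specific network-block pattern: its own within-network
        profile and a random subset of strong signed between-network
        blocks.  Blocks are large relative to windowed-correlation
        sampling noise so states are separable at window resolution."""
        within = {net: rng.uniform(0.35, 0.70) for net in nets}
        pairs = [(a, b) for i, a in enumerate(nets) for b in nets[i + 1:]]
        between = {}
        for pair in pairs:
            if rng.random() < 0.6:
                between[pair] = (rng.choice([-1.0, 1.0])
                                 * rng.uniform(0.25, 0.55))
            else:
                between[pair] = rng.uniform(-0.05, 0.05)
        return _block_matrix(parcellation, within, between, 0.0)

    def distinct_pattern(accepted, max_r: float = 0.5,
                         attempts: int = 200) -> np.ndarray:
        """Redraw until the new pattern's off-diagonal correlation with
        every accepted state stays below ``max_r`` — states must be
        distinct directions, not near-copies."""
        for _ in range(attempts):
            cand = signature_pattern()
            v = cand[iu]
            if all(abs(np.corrcoef(v, prev[iu])[0, 1]) <= max_r
                   for prev in accepted):
                return cand
        raise ConstructionError(
            f"could not draw a state pattern with |r| <= {max_r} "
            f"to all existing states")

    covs = [segregated]
    for _ in range(1, K - 1):
        covs.append(distinct_pattern(covs))
    sparse = distinct_pattern(covs)
    off = sparse - np.eye(parcellation.n_rois)
    # weak-amplitude version of its own pattern: sparsely connected but
    # still a correlated direction a centroid can recover
    sparse = np.eye(parcellation.n_rois) + 0.14 * off
    covs.append(sparse)
    covs = [nearest_correlation(np.clip(C, -0.95, 0.95)) for C in covs]
    for C in covs:
        np.fill_diagonal(C, 1.0)
    return StateSpec(covariances=covs, dwell_mean_windows=dwell_mean_windows,
                     base_occupancy=base_occupancy)


def _symmetric_noise(rng: np.random.Generator, R: int) -> np.ndarray:
    Z = rng.standard_normal((R, R))
    Z = (Z + Z.T) / 2.0
    np.fill_diagonal(Z, 0.0)
    return Z


# ---------------------------------------------------------------------------
# state dynamics


def transition_matrix(base_occupancy: np.ndarray,
                      dwell_mean_windows: float,
                      clip_feasible: bool = False) -> np.ndarray:
    """Reversible first-order Markov transition matrix with stationary
    distribution ``base_occupancy`` and run-averaged mean dwell
    ``dwell_mean_windows``.

    Off-diagonal flow between states i != j is proportional to
    ``pi_i * pi_j`` (detailed balance), scaled so that the mean run
    length, averaged over runs, equals the requested dwell.  A very
    rare state may make the requested dwell infeasible (its exit rate
    would exceed 1); with ``clip_feasible`` the flow rate is capped so
    the rare state simply dwells for single steps, otherwise a
    parameter error is raised.
    """
    pi = np.asarray(base_occupancy, dtype=float)
    K = len(pi)
    active = pi > 0
    if active.sum() == 1:
        P = np.eye(K)
        return P
    denom = 1.0 - np.sum(pi ** 2)
    kappa = 1.0 / (dwell_mean_windows * denom)
    kappa_max = 1.0 / (1.0 - pi[active].min())
    if kappa > kappa_max:
        if not clip_feasible:
            raise ParameterError(
                "dwell_mean_windows too short for this occupancy profile")
        kappa = kappa_max
    P = kappa * np.tile(pi, (K, 1))
    diag = 1.0 - kappa * (1.0 - pi)
    np.fill_diagonal(P, diag)
    P[~active, :] = 0.0
    P[~active, ~active] = 1.0
    return P


def simulate_state_sequence(spec: StateSpec, n_steps: int, seed: int,
                            occupancy: Optional[np.ndarray] = None,
                            clip_feasible: bool = False) -> np.ndarray:
    """Simulate the latent state chain for ``n_steps`` window-resolution
    steps.  ``occupancy`` overrides the spec's base occupancy (used for
    trait-shifted subjects, with ``clip_feasible`` so extreme shifts
    degrade the rare state's dwell instead of failing)."""
    if n_steps < 1:
        raise ParameterError("n_steps must be >= 1")
    pi = spec.base_occupancy if occupancy is None else np.asarray(occupancy)
    P = transition_matrix(pi, spec.dwell_mean_windows, clip_feasible)
    rng = np.random.default_rng(seed)
    states = np.empty(n_steps, dtype=np.int64)
    cum_pi = np.cumsum(pi)
    states[0] = np.searchsorted(cum_pi, rng.random(), side="right")
    cum_P = np.cumsum(P, axis=1)
    u = rng.random(n_steps - 1)
    for t in range(1, n_steps):
        states[t] = np.searchsorted(cum_P[states[t - 1]], u[t - 1],
                                    side="right")
    return np.clip(states, 0, spec.K - 1)


def shifted_occupancy(base: np.ndarray, occupancy_effect: float,
                      trait: float) -> np.ndarray:
    """Move occupancy mass between the first and last state by shifting
    the within-pair log-odds by ``occupancy_effect * trait``; states in
    between are untouched."""
    pi = np.asarray(base, dtype=float).copy()
    s = pi[0] + pi[-1]
    if s <= 0 or occupancy_effect * trait == 0 or pi[0] == 0 or pi[-1] == 0:
        return pi
    logit = np.log(pi[0] / pi[-1]) + occupancy_effect * trait
    pi[0] = s / (1.0 + np.exp(-logit))
    pi[-1] = s - pi[0]
    return pi


# ---------------------------------------------------------------------------
# subject- and cohort-level simulation


def simulate_subject(spec: StateSpec, cohort: CohortSpec, subject_trait: float,
                     seed) -> Tuple[List[RoiTimecourse], np.ndarray,
                                    List[np.ndarray]]:
    """Simulate all scans of one subject.

    Returns ``(scans, realized_occupancy, block_sequences)`` where
    ``realized_occupancy`` is the K-vector of TR fractions pooled over the
    subject's scans.  Time points are drawn i.i.d. from the zero-mean
    multivariate normal of the current state (the latent chain runs at
    window-block resolution and is expanded to TR resolution), plus
    isotropic white noise of sd ``noise_sd``.
    """
    rng = np.random.default_rng(seed)
    pi = shifted_occupancy(spec.base_occupancy, cohort.occupancy_effect,
                           subject_trait)
    chols = [np.linalg.cholesky(C) for C in spec.covariances]
    R = spec.n_rois
    n_blocks = int(np.ceil(cohort.T / cohort.block_len_tr))
    scans: List[RoiTimecourse] = []
    seqs: List[np.ndarray] = []
    counts = np.zeros(spec.K)
    for s in range(cohort.scans_per_subject):
        blocks = simulate_state_sequence(
            spec, n_blocks, seed=rng.integers(2 ** 31), occupancy=pi,
            clip_feasible=True)
        tr_states = np.repeat(blocks, cohort.block_len_tr)[: cohort.T]
        Z = rng.standard_normal((cohort.T, R))
        X = np.empty_like(Z)
        for k in range(spec.K):
            m = tr_states == k
            if m.any():
                X[m] = Z[m] @ chols[k].T
        if cohort.noise_sd > 0:
            X += cohort.noise_sd * rng.standard_normal(X.shape)
        motion = None
        if cohort.simulate_motion:
            steps = 0.02 * rng.standard_normal((cohort.T, 6))
            motion = np.cumsum(steps, axis=0)
        scans.append(RoiTimecourse(data=X, tr_seconds=cohort.tr_seconds,
                                   scan_id=f"scan{s + 1}", motion=motion))
        seqs.append(blocks)
        counts += np.bincount(tr_states, minlength=spec.K)
    occ = counts / counts.sum()
    return scans, occ, seqs


def _assign_sites_families(n: int, n_sites: int, families_per_site: int,
                           rng: np.random.Generator
                           ) -> Tuple[np.ndarray, np.ndarray]:
    sites = np.array([f"S{i % n_sites + 1:02d}" for i in range(n)])
    fam_idx = rng.integers(0, families_per_site, size=n)
    families = np.array([f"{s}_F{f + 1:02d}" for s, f in zip(sites, fam_idx)])
    return sites, families


def simulate_cohort(spec: StateSpec, cohort: CohortSpec,
                    cognitive_scores: Sequence[str] = (
                        "nihtbx_fluid", "nihtbx_cardsort", "nihtbx_totalcomp"),
                    psychiatric_scores: Sequence[str] = (
                        "cbcl_attention", "cbcl_adhd"),
                    ) -> Tuple[Dict[str, List[RoiTimecourse]], BehaviorTable,
                               SyntheticTruth]:
    """Simulate a full cohort: scans, behavior table and ground truth.

    Behavioral scores couple to the latent subject trait that shifts
    occupancy between the segregated and sparse states: cognitive scores
    negatively, psychiatric scores positively, calibrated so the
    correlation with realized segregated-state occupancy equals
    ``assoc_effect_r`` (the sparse state mirrors it with opposite sign;
    states the trait does not move are truly null).  The designated
    mediation triple overrides two columns:
    ``cbcl_attention`` (mediator M = a*occ + effects + noise) and
    ``nihtbx_fluid`` (outcome Y = c'*occ + b*M + effects + noise).
    """
    ss = np.random.SeedSequence(cohort.seed)
    children = ss.spawn(cohort.n_subjects + 1)
    rng = np.random.default_rng(children[-1])
    n = cohort.n_subjects

    traits = rng.standard_normal(n)
    subject_ids = [f"sub{i + 1:04d}" for i in range(n)]
    scans: Dict[str, List[RoiTimecourse]] = {}
    realized = np.empty((n, spec.K))
    expected = np.empty((n, spec.K))
    block_seqs: Dict[str, List[List[int]]] = {}
    for i, sid in enumerate(subject_ids):
        expected[i] = shifted_occupancy(spec.base_occupancy,
                                        cohort.occupancy_effect, traits[i])
        subj_scans, occ, seqs = simulate_subject(spec, cohort, traits[i],
                                                 seed=children[i])
        for sc in subj_scans:
            sc.subject_id = sid
            sc.session_id = "ses1"
        scans[sid] = subj_scans
        realized[i] = occ
        block_seqs[sid] = [s.tolist() for s in seqs]

    sites, families = _assign_sites_families(
        n, cohort.n_sites, cohort.families_per_site, rng)
    site_levels = np.unique(sites)
    fam_levels = np.unique(families)

    # covariates with plausible ranges and small nuisance effects
    age = rng.uniform(108, 132, size=n)            # months, 9-11 y
    gender = rng.choice(["F", "M"], size=n)
    race = rng.choice(["A", "B", "C"], size=n, p=[0.55, 0.25, 0.20])
    height = 120 + 0.15 * (age - 120) + rng.normal(0, 6, size=n)   # cm
    weight = 30 + 0.25 * (height - 140) + rng.normal(0, 5, size=n)  # kg

    zocc = _zscore(realized[:, 0])
    ztrait = _zscore(traits)

    def random_effects() -> np.ndarray:
        u_site = dict(zip(site_levels,
                          cohort.site_sd * rng.standard_normal(len(site_levels))))
        u_fam = dict(zip(fam_levels,
                         cohort.family_sd * rng.standard_normal(len(fam_levels))))
        return (np.array([u_site[s] for s in sites])
                + np.array([u_fam[f] for f in families]))

    # Scores couple to the latent trait, never to realized occupancy, so
    # states whose expected occupancy the trait does not move stay truly
    # null.  The trait-level coupling is calibrated against the realized
    # trait->occupancy correlation so that corr(score, occ_state0) hits
    # the requested assoc_effect_r (capped at the attainable maximum).
    r = cohort.assoc_effect_r
    trait_occ_corr = float(np.corrcoef(ztrait, realized[:, 0])[0, 1]) \
        if cohort.occupancy_effect != 0 and n > 2 else 0.0
    q = min(0.98, abs(r) / max(abs(trait_occ_corr), 1e-6)) * np.sign(r)
    var_rest = 1.0 + cohort.site_sd ** 2 + cohort.family_sd ** 2
    beta = q * np.sqrt(var_rest / max(1.0 - q ** 2, 1e-9))

    cols: Dict[str, np.ndarray] = {}
    couplings: Dict[str, float] = {}
    nuisance = 0.01 * (age - 120) - 0.01 * (height - 140)
    for name in cognitive_scores:
        cols[name] = (-beta * ztrait + nuisance + random_effects()
                      + rng.standard_normal(n))
        couplings[name] = -r
    for name in psychiatric_scores:
        cols[name] = (beta * ztrait + nuisance + random_effects()
                      + rng.standard_normal(n))
        couplings[name] = r

    # mediation triple: occ -> cbcl_attention -> nihtbx_fluid
    med = cohort.mediation
    a, b, c_prime = med["a"], med["b"], med["c_prime"]
    M = a * zocc + nuisance + random_effects() + rng.standard_normal(n)
    Y = (c_prime * zocc + b * M + nuisance + random_effects()
         + rng.standard_normal(n))
    if "cbcl_attention" in cols:
        cols["cbcl_attention"] = M
        couplings["cbcl_attention"] = a
    if "nihtbx_fluid" in cols:
        cols["nihtbx_fluid"] = Y
        couplings["nihtbx_fluid"] = c_prime + a * b
    true_ab = a * b
    c_total = c_prime + a * b
    prop_med = true_ab / c_total if c_total != 0 else (
        1.0 if true_ab != 0 else 0.0)

    import pandas as pd
    table = pd.DataFrame({
        "subject_id": subject_ids, "site_id": sites, "family_id": families,
        "age": age, "gender": gender, "race": race,
        "height": height, "weight": weight, **cols,
    })
    behavior = BehaviorTable(table=table,
                             cognitive_scores=list(cognitive_scores),
                             psychiatric_scores=list(psychiatric_scores))
    truth = SyntheticTruth(
        covariances=spec.covariances,
        base_occupancy=spec.base_occupancy,
        subject_ids=subject_ids,
        traits=traits,
        expected_occupancy=expected,
        realized_occupancy=realized,
        block_sequences=block_seqs,
        assoc_effect_r=cohort.assoc_effect_r,
        score_couplings=couplings,
        mediation_paths=dict(med),
        true_ab=true_ab,
        true_proportion_mediated=prop_med,
        seed=cohort.seed,
    )
    return scans, behavior, truth


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()
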
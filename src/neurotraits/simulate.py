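"""Synthetic chronic-pain cohorts with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume: 36 questionnaire subscales driven by four orthogonal latent
factors with block loadings; 272-node Fisher-z connectivity matrices
with trait-correlated edges planted at a configurable population
correlation; four repeat imaging sessions whose between/within-subject
variance ratio is set by a target intraclass correlation; pain measures
cross-loading on the pain factor (factor 1) and, negatively, the
emotional-resilience factor (factor 4); and income categories linked to
factor 1 through a latent threshold model.

Every stage draws from a child seed spawned from the single cohort seed,
so regeneration with the same config is bit-identical and stages can be
regenerated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

# Stage order for child-seed spawning; fixed, never reordered.
_STAGES = ("questionnaires", "connectivity", "pain", "demographics", "motion", "ica")

#: Yearly self-reported income brackets (US dollars).
INCOME_CATEGORIES = ("0-10,000", "10,000-25,000", "25,000-50,000", ">50,000")

ETHNICITY_CATEGORIES = ("WA", "AA", "HA")

#: SD of the non-trait (subject + session) noise on a connectivity edge,
#: on the Fisher-z scale.  Typical between-subject spread of resting-state
#: edge values.
EDGE_NOISE_SD = 0.10

#: Mean and spread of the shared background connectome (Fisher-z).
BACKGROUND_MEAN = 0.25
BACKGROUND_SD = 0.30


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort.

    Defaults reproduce the study conditions the package is tested under:
    62 subjects, 36 subscales from 4 orthogonal factors, 272 parcellation
    nodes in 14 communities, 4 imaging sessions.
    """

    n_subjects: int = 62
    n_subscales: int = 36
    n_factors: int = 4
    loading_magnitude: float = 0.7
    uniqueness_sd: Optional[float] = None
    n_nodes: int = 272
    n_communities: int = 14
    planted_edges_per_trait: int = 50
    edge_effect: float = 0.5
    n_sessions: int = 4
    session_icc: float = 0.85
    n_timepoints: int = 1110
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_subscales", "n_factors", "n_nodes",
                     "n_communities", "planted_edges_per_trait", "n_sessions",
                     "n_timepoints"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.loading_magnitude < 1:
            raise ValueError("loading_magnitude must be in [0, 1)")
        if abs(self.edge_effect) >= 1:
            raise ValueError("edge_effect is a correlation; |edge_effect| must be < 1")
        if not 0 <= self.session_icc <= 1:
            raise ValueError("session_icc must be in [0, 1]")
        if self.n_subscales < self.n_factors:
            raise ValueError("need at least one subscale per factor")
        if self.uniqueness_sd is None:
            # unit total variance per subscale for loaded subscales
            self.uniqueness_sd = math.sqrt(1.0 - self.loading_magnitude**2)
        if self.uniqueness_sd < 0:
            raise ValueError("uniqueness_sd must be >= 0")

    def rng(self, stage: str) -> np.random.Generator:
        """Child generator for a named stage (counter-based spawning)."""
        idx = _STAGES.index(stage)
        ss = np.random.SeedSequence(self.seed, spawn_key=(idx,))
        return np.random.default_rng(ss)


def factor_loading_matrix(cfg: CohortConfig) -> np.ndarray:
    """Ground-truth block loading matrix (n_subscales x n_factors).

    Subscales are partitioned into ``n_factors`` contiguous blocks of
    near-equal size; each subscale loads ``loading_magnitude`` on its
    block's factor and 0 elsewhere.
    """
    L = np.zeros((cfg.n_subscales, cfg.n_factors))
    blocks = np.array_split(np.arange(cfg.n_subscales), cfg.n_factors)
    for k, idx in enumerate(blocks):
        L[idx, k] = cfg.loading_magnitude
    return L


def population_subscale_covariance(cfg: CohortConfig) -> np.ndarray:
    """Analytic covariance of the subscale generator: Lambda Lambda' + sigma^2 I."""
    L = factor_loading_matrix(cfg)
    return L @ L.T + cfg.uniqueness_sd**2 * np.eye(cfg.n_subscales)


def generate_questionnaires(cfg: CohortConfig) -> Tuple[pd.DataFrame, np.ndarray]:
    """Draw subscale scores from the linear factor model.

    subscale_j = sum_k lambda_jk f_k + eps_j, with independent standard
    normal factors and N(0, uniqueness_sd^2) uniqueness.

    Returns
    -------
    subscales : DataFrame (n_subjects x n_subscales), columns s01..
    factors : ndarray (n_subjects x n_factors), the true factor scores.
    """
    rng = cfg.rng("questionnaires")
    F = rng.standard_normal((cfg.n_subjects, cfg.n_factors))
    L = factor_loading_matrix(cfg)
    E = rng.standard_normal((cfg.n_subjects, cfg.n_subscales)) * cfg.uniqueness_sd
    X = F @ L.T + E
    cols = [f"s{j + 1:02d}" for j in range(cfg.n_subscales)]
    return pd.DataFrame(X, columns=cols), F


def n_edges(n_nodes: int) -> int:
    """Unique undirected edges over the strict upper triangle."""
    return n_nodes * (n_nodes - 1) // 2


@dataclass
class ConnectivityEnsemble:
    """Edge-vector form of per-subject per-session connectivity.

    ``edge_values[i, s]`` is the strict-upper-triangle Fisher-z vector of
    subject i, session s, ordered like ``np.triu_indices(n_nodes, 1)``.
    """

    edge_values: np.ndarray  # (n_subjects, n_sessions, E)
    n_nodes: int

    @property
    def edge_index(self) -> Tuple[np.ndarray, np.ndarray]:
        return np.triu_indices(self.n_nodes, 1)

    def matrix(self, subject: int, session: int = 0) -> np.ndarray:
        """Reconstruct the symmetric zero-diagonal matrix of one scan."""
        P = self.n_nodes
        M = np.zeros((P, P))
        iu, ju = self.edge_index
        M[iu, ju] = self.edge_values[subject, session]
        return M + M.T

    def session(self, session: int) -> np.ndarray:
        """(n_subjects, E) edge matrix of one session."""
        return self.edge_values[:, session, :]


@dataclass
class PlantedEdges:
    """Ground-truth planted edge indices per trait and sign."""

    positive: Dict[int, np.ndarray] = field(default_factory=dict)
    negative: Dict[int, np.ndarray] = field(default_factory=dict)


def generate_connectivity(
    cfg: CohortConfig, factors: np.ndarray
) -> Tuple[ConnectivityEnsemble, PlantedEdges]:
    """Connectivity with trait-correlated planted edges.

    Planted edge e of trait k carries z_e = background + beta * f_k +
    noise with sign(beta) per list; ``edge_effect`` is the population
    correlation between the edge and the trait in a single session.  The
    non-trait noise splits into a subject-level intercept and a session
    deviation sized so that sigma_b^2 / (sigma_b^2 + sigma_w^2) equals
    ``session_icc``.
    """
    if cfg.n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    E = n_edges(cfg.n_nodes)
    total_planted = 2 * cfg.planted_edges_per_trait * cfg.n_factors
    if total_planted > E:
        raise ValueError("more planted edges requested than edges available")

    rng = cfg.rng("connectivity")
    n, S = cfg.n_subjects, cfg.n_sessions

    background = rng.normal(BACKGROUND_MEAN, BACKGROUND_SD, size=E)
    chosen = rng.choice(E, size=total_planted, replace=False)
    planted = PlantedEdges()
    pos = 0
    for k in range(cfg.n_factors):
        planted.positive[k] = np.sort(chosen[pos:pos + cfg.planted_edges_per_trait])
        pos += cfg.planted_edges_per_trait
        planted.negative[k] = np.sort(chosen[pos:pos + cfg.planted_edges_per_trait])
        pos += cfg.planted_edges_per_trait

    r = cfg.edge_effect
    beta = abs(r) * EDGE_NOISE_SD / math.sqrt(1.0 - r**2) if r != 0 else 0.0
    sigma_b = math.sqrt(cfg.session_icc) * EDGE_NOISE_SD
    sigma_w = math.sqrt(1.0 - cfg.session_icc) * EDGE_NOISE_SD

    signal = np.zeros((n, E))
    for k in range(cfg.n_factors):
        f = factors[:, k]
        signal[:, planted.positive[k]] += beta * f[:, None]
        signal[:, planted.negative[k]] -= beta * f[:, None]

    intercept = rng.standard_normal((n, E)) * sigma_b
    values = np.empty((n, S, E))
    for s in range(S):
        dev = rng.standard_normal((n, E)) * sigma_w if sigma_w > 0 else 0.0
        values[:, s, :] = background[None, :] + signal + intercept + dev
    return ConnectivityEnsemble(values, cfg.n_nodes), planted


#: Pain/clinical measures and their default cross-loadings on
#: (factor 1, factor 4).  Intensity measures load on the pain factor;
#: negative-affect measures load on the pain factor and negatively on
#: the emotional-resilience factor; physical health loads negatively on
#: the pain factor.
DEFAULT_PAIN_LOADINGS: Dict[str, Tuple[float, float]] = {
    "ema": (0.5, 0.0),
    "memory": (0.5, 0.0),
    "nrs": (0.5, 0.0),
    "mpq_s": (0.4, 0.0),
    "mpq_a": (0.4, 0.0),
    "paindetect": (0.4, 0.0),
    "panas_n": (0.4, -0.4),
    "bdi": (0.4, -0.4),
    "sf12p": (-0.3, 0.0),
}

PAIN_NOISE_SD = 1.0


def generate_pain_and_demographics(
    cfg: CohortConfig,
    factors: np.ndarray,
    pain_loadings: Optional[Dict[str, Tuple[float, float]]] = None,
    income_effect: float = -0.4,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Pain measures and demographics linked to the latent factors.

    Each pain measure m = a_m * f1 + b_m * f4 + noise.  Income is an
    ordinal draw from the four categories through a latent variable
    y* = income_effect * f1 + eps cut at its population quartiles, so a
    negative ``income_effect`` places high pain-trait subjects in lower
    brackets.  Years of education and race/ethnicity are generated from
    the income bracket (associated with income, not with the factors);
    sex is independent.
    """
    if pain_loadings is None:
        pain_loadings = DEFAULT_PAIN_LOADINGS
    n = cfg.n_subjects
    f1 = factors[:, 0]
    f4 = factors[:, min(3, cfg.n_factors - 1)]

    rng = cfg.rng("pain")
    pain = {}
    for name, (a, b) in pain_loadings.items():
        pain[name] = a * f1 + b * f4 + rng.standard_normal(n) * PAIN_NOISE_SD
    pain_df = pd.DataFrame(pain)

    rng_d = cfg.rng("demographics")
    latent_sd = math.sqrt(income_effect**2 + 1.0)
    latent = income_effect * f1 + rng_d.standard_normal(n)
    from scipy.stats import norm

    cuts = norm.ppf([0.25, 0.5, 0.75]) * latent_sd
    income_code = np.digitize(latent, cuts)  # 0..3, 0 = lowest bracket
    education = np.clip(
        np.round(12 + 1.2 * income_code + rng_d.normal(0, 2, n)), 8, 20
    ).astype(int)
    eth_probs = np.array([0.45, 0.35, 0.20])
    ethnicity = rng_d.choice(ETHNICITY_CATEGORIES, size=n, p=eth_probs)
    sex = rng_d.choice(["F", "M"], size=n)
    demo = pd.DataFrame(
        {
            "income": [INCOME_CATEGORIES[c] for c in income_code],
            "income_code": income_code,
            "education_years": education,
            "ethnicity": ethnicity,
            "sex": sex,
        }
    )
    return pain_df, demo


def generate_motion(cfg: CohortConfig) -> np.ndarray:
    """Per-subject mean framewise displacement (mm), independent of traits.

    Centered on the low-motion regime typical of multiband resting-state
    acquisitions (mean ~0.11 mm, SD ~0.07), truncated below at 0.01 mm.
    """
    rng = cfg.rng("motion")
    return np.maximum(rng.normal(0.11, 0.07, size=cfg.n_subjects), 0.01)


def generate_nodes(cfg: CohortConfig) -> pd.DataFrame:
    """Parcellation table: node id, pseudo-MNI coordinates, community label.

    Communities are contiguous blocks of near-equal size; coordinates are
    placeholder points on a sphere (the analyses only use the labels).
    """
    rng = cfg.rng("connectivity")  # coordinates carry no signal
    blocks = np.array_split(np.arange(cfg.n_nodes), cfg.n_communities)
    community = np.empty(cfg.n_nodes, dtype=int)
    for c, idx in enumerate(blocks):
        community[idx] = c
    xyz = rng.normal(0, 40, size=(cfg.n_nodes, 3))
    return pd.DataFrame(
        {
            "node": np.arange(cfg.n_nodes),
            "x": np.round(xyz[:, 0], 1),
            "y": np.round(xyz[:, 1], 1),
            "z": np.round(xyz[:, 2], 1),
            "community": community,
        }
    )


@dataclass
class SyntheticCohort:
    """A jointly generated cohort with full ground truth."""

    config: CohortConfig
    subscales: pd.DataFrame
    true_factor_scores: np.ndarray
    true_loadings: np.ndarray
    connectivity: ConnectivityEnsemble
    planted_edges: PlantedEdges
    pain_measures: pd.DataFrame
    demographics: pd.DataFrame
    motion: np.ndarray
    nodes: pd.DataFrame


def generate_cohort(cfg: CohortConfig) -> SyntheticCohort:
    """Generate all cohort components from one config/seed."""
    subscales, F = generate_questionnaires(cfg)
    conn, planted = generate_connectivity(cfg, F)
    pain, demo = generate_pain_and_demographics(cfg, F)
    return SyntheticCohort(
        config=cfg,
        subscales=subscales,
        true_factor_scores=F,
        true_loadings=factor_loading_matrix(cfg),
        connectivity=conn,
        planted_edges=planted,
        pain_measures=pain,
        demographics=demo,
        motion=generate_motion(cfg),
        nodes=generate_nodes(cfg),
    )


def generate_session_scores(
    n_subjects: int,
    n_sessions: int,
    between_sd: float,
    within_sd: float,
    seed: int,
) -> np.ndarray:
    """Random-intercept session scores for reliability studies.

    score_{is} = b_i + w_{is}, b ~ N(0, between_sd^2), w ~ N(0,
    within_sd^2).  The population single-measures ICC is
    between_sd^2 / (between_sd^2 + within_sd^2).
    """
    rng = np.random.default_rng(seed)
    b = rng.normal(0, between_sd, size=n_subjects)
    w = rng.normal(0, within_sd, size=(n_subjects, n_sessions))
    return b[:, None] + w


# ---------------------------------------------------------------------------
# ICA component fixtures


@dataclass
class ComponentFixture:
    """A spatial map plus masks and a time course for the ICA noise rules."""

    spatial_map: np.ndarray  # boolean activation grid
    edge_mask: np.ndarray
    wm_mask: np.ndarray
    vent_mask: np.ndarray
    timecourse: np.ndarray
    tr: float
    name: str = ""


def _grid_masks(size: int = 20) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Edge / white-matter / ventricle masks on a square voxel grid."""
    edge = np.zeros((size, size), dtype=bool)
    edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
    wm = np.zeros((size, size), dtype=bool)
    wm[4:8, 4:16] = True
    vent = np.zeros((size, size), dtype=bool)
    vent[12:15, 8:12] = True
    return edge, wm, vent


def _sinusoid(freq_hz: float, tr: float, n: int, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) * tr
    return np.sin(2 * np.pi * freq_hz * t + rng.uniform(0, 2 * np.pi))


def generate_ica_fixture(seed: int = 0, tr: float = 0.555, n_timepoints: int = 990
                         ) -> List[ComponentFixture]:
    """Deterministic component fixtures with known rule outcomes.

    Returns four components: a clean interior low-frequency component
    (kept), an edge-dominated one (edge ratio 0.5), a white-matter/
    ventricle one, and a high-frequency one (0.08 Hz carrier).
    """
    rng = np.random.default_rng(seed)
    edge, wm, vent = _grid_masks()
    size = edge.shape[0]

    def blank() -> np.ndarray:
        return np.zeros((size, size), dtype=bool)

    low = _sinusoid(0.02, tr, n_timepoints, rng)
    high = _sinusoid(0.08, tr, n_timepoints, rng)

    clean = blank()
    clean[9:12, 2:6] = True  # interior, off the masks

    edgy = blank()
    edgy[0, 0:10] = True           # 10 edge voxels
    edgy[10, 2:12] = True          # 10 interior voxels -> ratio 0.5

    wmv = blank()
    wmv[4:8, 4:16] = True          # the full WM block active

    hf = blank()
    hf[16:18, 2:6] = True

    mk = lambda m, tc, name: ComponentFixture(m, edge, wm, vent, tc, tr, name)
    return [
        mk(clean, low, "clean_interior"),
        mk(edgy, low, "edge_dominated"),
        mk(wmv, low, "wm_ventricle"),
        mk(hf, high, "high_frequency"),
    ]
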
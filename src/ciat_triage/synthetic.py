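"""Seeded synthetic HTS campaigns with planted interference chemotypes.

Real counter-screen (artefact) datasets for assay-technology interference
are proprietary, so the package ships a generator that emulates their
structure: several detection technologies, each with a handful of primary
assays followed up by an artefact assay, plus a larger pool of primary
assays without artefact follow-up; compounds tested in one or several
assays; and a planted structure→interference relationship driven by
technology-specific substructure motifs (e.g. quinones for singlet-oxygen
based luminescence, azo dyes for fluorescence quenching, 1,3-diketone metal
chelators for lanthanide-based readouts).

Compounds that interfere with a technology (CIATs) produce false-positive
readouts in that technology's primary assays with a configurable
penetrance, and score active in the technology's artefact assays up to a
small flip noise.  The fraction of CIATs among primary actives is
calibrated to a target prevalence, by default 22.4 %.

All randomness flows from a single seed through named substreams
(library, truth, assignment, noise), so identical configurations yield
byte-identical campaigns.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem import mol_from_smiles

__all__ = [
    "GeneratorConfig",
    "SyntheticCampaign",
    "CalibrationError",
    "MotifError",
    "generate_library",
    "assign_ground_truth",
    "simulate_campaign",
    "write_campaign",
    "read_campaign",
    "DEFAULT_MOTIFS",
]


class CalibrationError(RuntimeError):
    """Raised when the CIAT prevalence target cannot be reached."""


class MotifError(ValueError):
    """Raised when a requested motif cannot be planted into the library."""


# Interference chemotypes with a mechanistic rationale per detection
# technology, written as (SMARTS used for carrier checks, SMILES fragment
# inserted into the scaffold templates).  The default trio is deliberately
# disjoint from the PAINS catalog: in curated counter-screen data PAINS
# alerts recover only a small minority of technology interferers, and the
# generator emulates that regime.
DEFAULT_MOTIFS: dict[str, tuple[str, str]] = {
    # aryl benzyl thioethers: singlet-oxygen quenchers (bead-based
    # chemiluminescence such as AlphaScreen).
    "SCc1ccccc1": ("SCc1ccccc1", "SCc3ccccc3"),
    # nitroaromatics: broad-band fluorescence quenchers (FRET).
    "[N+](=O)[O-]": ("[N+](=O)[O-]", "[N+](=O)[O-]"),
    # 1,3-diketones: chelators competing with lanthanide complexes (TR-FRET).
    "CC(=O)CC(C)=O": ("CC(=O)CC(C)=O", "C(C(C)=O)C(C)=O"),
    # extra chemotypes selectable via motif_smarts; these two are also
    # PAINS patterns (quinone_A, azo_A), useful for studying the overlap
    "O=C1C=CC(=O)C=C1": ("O=C1C=CC(=O)C=C1", "C3=CC(=O)C=CC3=O"),
    "cN=Nc": ("cN=Nc", "N=Nc3ccccc3"),
}

_DEFAULT_MOTIF_ORDER = list(DEFAULT_MOTIFS)[:3]

# Scaffold templates with a motif/benign slot {m} and a tail slot {t}.
_TEMPLATES = [
    "c1ccc({m})cc1{t}",
    "c1cc({m})ccc1{t}",
    "c1ccc({m})nc1{t}",
    "c1cnc({m})cc1{t}",
    "C1CCC({m})CC1{t}",
    "c1cc({m})sc1{t}",
]

_RING_DECORATIONS = ["", "F", "Cl", "C", "OC", "C(F)(F)F", "C#N", "N"]

_BENIGN_MIDS = [
    "C",
    "CC",
    "CCC",
    "CCO",
    "C(C)C",
    "C(C)(C)C",
    "CN(C)C",
    "CC(C)=O",
    "CCC(C)=O",
    "COC",
    "CCOC",
    "OC",
    "OCC",
    "N(C)C",
    "CCN",
    "C(F)(F)F",
    "CC#N",
    "CC(N)=O",
    "c3ccccc3",
    "C3CCCCC3",
    "N3CCOCC3",
    "CNC(C)=O",
    # catechol: a PAINS chemotype planted independently of interference, so
    # substructure alerts fire on a small label-uncorrelated background
    "c3ccc(O)c(O)c3",
]

_TAIL_CHAINS = [
    "C", "CC", "CCC", "CCCC", "CCCCC", "CCCCCC", "CCCCCCC", "CCCCCCCC",
    "CC(C)", "CC(C)C", "CCC(C)", "CC(CC)", "CCC(C)C", "CCCC(C)", "CC(C)CC",
    "CCC(CC)", "CCCCC(C)", "CC(C)CCC", "CCCC(C)C", "CC(C)C(C)",
]
_TAIL_TERMINALS = [
    "", "O", "N", "F", "Cl", "Br", "OC", "N(C)C", "OCC", "C#N",
    "C(F)(F)F", "C(C)O", "NCC", "N(C)CC", "OC(C)C", "C(N)=O", "OCCO", "N(CC)CC",
]

_FLAG_ACTIVE = "active"
_FLAG_INACTIVE = "inactive"
_FLAG_INCONCLUSIVE = "inconclusive"


def _decorated_templates() -> list[str]:
    out = []
    for tpl in _TEMPLATES:
        for deco in _RING_DECORATIONS:
            if deco and tpl.startswith("c1cc("):
                # decorate only benzene-like templates to keep valences safe
                continue
            if deco and not tpl.startswith("c1ccc({m})cc1"):
                continue
            if deco:
                out.append("c1cc(" + deco + ")cc({m})c1{t}")
            else:
                out.append(tpl)
    # dedupe while preserving order
    seen: set[str] = set()
    uniq = []
    for t in out:
        if t not in seen:
            seen.add(t)
            uniq.append(t)
    return uniq


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic screening campaign.

    Parameters
    ----------
    n_compounds:
        Library size (unique, parseable structures).
    technologies:
        Detection technology names; technology *i* is driven by
        ``motif_smarts[i]``.
    n_primary_assays:
        Artefact-linked primary assays per technology (each has exactly one
        linked artefact assay).
    n_extra_primary_assays:
        Additional primary assays per technology without artefact
        follow-up.  They contribute screening history for the promiscuity
        score but never labels.
    motif_smarts:
        One interference motif per technology (SMARTS).  For motifs outside
        the built-in table, matching SMILES fragments must be supplied via
        ``motif_fragments``.
    motif_fraction:
        Fraction of the library planted with each technology's motif
        (fractions are disjoint: a compound carries at most one motif).
    p_ciat_given_motif / p_ciat_no_motif:
        Ground-truth interference probability for motif carriers /
        non-carriers, before prevalence calibration.
    base_hit_rate:
        Per-assay probability that a compound is a true primary active.
    ciat_primary_hit_rate:
        Per-assay penetrance of interference: probability that a CIAT
        scores (falsely) active in one primary assay of its technology.
    artefact_flip_noise:
        Probability that an artefact readout contradicts the ground truth.
    multiplicity_dist:
        Distribution of the number of artefact-linked primary assays a
        compound is tested in (must give mass to 1 and to >1 for Set A and
        Set B to both arise).
    extra_multiplicity_dist:
        Same for the unlinked primary assays; mass at 0 allowed.
    target_ciat_prevalence:
        Target CIAT fraction among primary actives; ``None`` disables
        calibration.  Default 0.224.
    """

    n_compounds: int = 20_000
    technologies: tuple[str, ...] = ("AlphaScreen", "FRET", "TR-FRET")
    n_primary_assays: int = 8
    n_extra_primary_assays: int = 20
    motif_smarts: tuple[str, ...] = tuple(_DEFAULT_MOTIF_ORDER)
    motif_fragments: Mapping[str, str] | None = None
    motif_fraction: float = 0.15
    p_ciat_given_motif: float = 0.25
    p_ciat_no_motif: float = 0.00625
    base_hit_rate: float = 0.05
    ciat_primary_hit_rate: float = 0.45
    artefact_flip_noise: float = 0.05
    p_extra_percent_flag: float = 0.10
    p_inconclusive: float = 0.01
    multiplicity_dist: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.60, 2: 0.25, 3: 0.15}
    )
    extra_multiplicity_dist: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.85, 1: 0.12, 2: 0.03}
    )
    target_ciat_prevalence: float | None = 0.224
    prevalence_tolerance: float = 0.05
    calibration_retries: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds <= 0:
            raise ValueError("n_compounds must be positive")
        if self.n_primary_assays <= 0:
            raise ValueError("n_primary_assays must be positive")
        if self.n_extra_primary_assays < 0:
            raise ValueError("n_extra_primary_assays must be >= 0")
        if len(self.motif_smarts) < len(self.technologies):
            raise ValueError("need one motif per technology")
        probs = {
            "motif_fraction": self.motif_fraction,
            "p_ciat_given_motif": self.p_ciat_given_motif,
            "p_ciat_no_motif": self.p_ciat_no_motif,
            "base_hit_rate": self.base_hit_rate,
            "ciat_primary_hit_rate": self.ciat_primary_hit_rate,
            "artefact_flip_noise": self.artefact_flip_noise,
            "p_extra_percent_flag": self.p_extra_percent_flag,
            "p_inconclusive": self.p_inconclusive,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.motif_fraction * len(self.technologies) > 1.0:
            raise ValueError("motif fractions across technologies exceed 1")
        if self.target_ciat_prevalence is not None and not (
            0.0 <= self.target_ciat_prevalence <= 1.0
        ):
            raise ValueError("target_ciat_prevalence must be in [0, 1]")
        self._check_dist(self.multiplicity_dist, lo=1, hi=self.n_primary_assays)
        if self.n_extra_primary_assays > 0:
            self._check_dist(
                self.extra_multiplicity_dist, lo=0, hi=self.n_extra_primary_assays
            )

    @staticmethod
    def _check_dist(dist: Mapping[int, float], lo: int, hi: int) -> None:
        if not dist:
            raise ValueError("multiplicity distribution must not be empty")
        total = float(sum(dist.values()))
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"multiplicity distribution must sum to 1, got {total}")
        for k, p in dist.items():
            if not (lo <= int(k) <= hi):
                raise ValueError(
                    f"multiplicity {k} outside the valid range [{lo}, {hi}]"
                )
            if p < 0:
                raise ValueError("multiplicity probabilities must be >= 0")

    def motif_fragment(self, smarts: str) -> str:
        table = dict(DEFAULT_MOTIFS)
        if self.motif_fragments:
            table.update(
                {s: (s, frag) for s, frag in self.motif_fragments.items()}
            )
        if smarts not in table:
            raise MotifError(
                f"no SMILES fragment known for motif {smarts!r}; "
                "provide one via motif_fragments"
            )
        return table[smarts][1]


@dataclass
class SyntheticCampaign:
    """One simulated screening campaign.

    Attributes
    ----------
    compounds: ``compound_id, smiles`` table.
    assays: ``assay_id, technology, assay_kind, linked_artefact_id`` table;
        every artefact-linked primary has exactly one artefact assay.
    results: long table of per-(compound, assay) outcomes with flag source.
    ground_truth: ``compound_id, technology, has_motif, is_ciat``.
    """

    config: GeneratorConfig
    compounds: pd.DataFrame
    assays: pd.DataFrame
    results: pd.DataFrame
    ground_truth: pd.DataFrame
    calibrated_p_ciat: tuple[float, float] | None = None

    def linked_primary_assays(self, technology: str) -> list[str]:
        a = self.assays
        mask = (
            (a["technology"] == technology)
            & (a["assay_kind"] == "primary")
            & a["linked_artefact_id"].notna()
        )
        return sorted(a.loc[mask, "assay_id"])

    def primary_assays(self, technology: str) -> list[str]:
        a = self.assays
        mask = (a["technology"] == technology) & (a["assay_kind"] == "primary")
        return sorted(a.loc[mask, "assay_id"])

    def ground_truth_map(self) -> dict[str, dict[str, str]]:
        out: dict[str, dict[str, str]] = {}
        for row in self.ground_truth.itertuples():
            out.setdefault(row.compound_id, {})[row.technology] = (
                "CIAT" if row.is_ciat else "NCIAT"
            )
        return out


def _substreams(seed: int, attempt: int = 0) -> dict[str, np.random.Generator]:
    """Named, independent random substreams derived from one seed."""
    names = ("library", "truth", "assignment", "noise")
    root = np.random.SeedSequence(entropy=seed, spawn_key=(attempt,))
    children = root.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def generate_library(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Enumerate a unique, parseable combinatorial library.

    Structures are scaffold+substituent combinations drawn from a small
    hand-written fragment list; a ``motif_fraction`` share of compounds per
    technology carries that technology's interference motif.  Returns a
    table with ``compound_id, smiles, motif`` (motif SMARTS or empty).
    """
    if rng is None:
        rng = _substreams(config.seed)["library"]
    templates = _decorated_templates()
    tails = [c + t for c in _TAIL_CHAINS for t in _TAIL_TERMINALS]
    motifs = list(config.motif_smarts[: len(config.technologies)])
    motif_mids = {sm: config.motif_fragment(sm) for sm in motifs}

    # verify each motif fragment actually carries its own pattern
    for sm, mid in motif_mids.items():
        probe = templates[0].format(m=mid, t="C")
        mol = Chem.MolFromSmiles(probe)
        query = Chem.MolFromSmarts(sm)
        if mol is None or query is None or not mol.HasSubstructMatch(query):
            raise MotifError(
                f"motif {sm!r}: fragment {mid!r} does not plant the pattern"
            )

    cut = np.cumsum([config.motif_fraction] * len(motifs))
    seen: set[str] = set()
    ids, smiles_list, motif_col = [], [], []
    max_tries = 80 * config.n_compounds
    tries = 0
    while len(ids) < config.n_compounds:
        tries += 1
        if tries > max_tries:
            raise MotifError(
                "could not enumerate enough unique structures; "
                f"got {len(ids)} of {config.n_compounds} "
                "(fragment space too small for the requested library)"
            )
        u = rng.random()
        motif_idx = int(np.searchsorted(cut, u, side="right"))
        if motif_idx < len(motifs):
            mid = motif_mids[motifs[motif_idx]]
            motif = motifs[motif_idx]
        else:
            mid = _BENIGN_MIDS[rng.integers(len(_BENIGN_MIDS))]
            motif = ""
        tpl = templates[rng.integers(len(templates))]
        tail = tails[rng.integers(len(tails))]
        smi = tpl.format(m=mid, t=tail)
        mol = Chem.MolFromSmiles(smi)
        if mol is None:  # pragma: no cover - fragment grammar is valid
            continue
        can = Chem.MolToSmiles(mol)
        if can in seen:
            continue
        seen.add(can)
        ids.append(f"C{len(ids):06d}")
        smiles_list.append(can)
        motif_col.append(motif)
    return pd.DataFrame(
        {"compound_id": ids, "smiles": smiles_list, "motif": motif_col}
    )


def _motif_carriers(
    compounds: pd.DataFrame, motif_smarts: Sequence[str]
) -> dict[str, np.ndarray]:
    """Carrier status per motif, determined by actual substructure matching."""
    mols = [mol_from_smiles(s) for s in compounds["smiles"]]
    out = {}
    for sm in motif_smarts:
        query = Chem.MolFromSmarts(sm)
        if query is None:
            raise MotifError(f"could not parse motif SMARTS {sm!r}")
        out[sm] = np.array([m.HasSubstructMatch(query) for m in mols], dtype=bool)
    return out


def assign_ground_truth(
    compounds: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    p_ciat: tuple[float, float] | None = None,
    carriers: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Draw per-technology CIAT ground truth.

    Per technology, ``P(CIAT) = p_ciat_given_motif`` for carriers of that
    technology's motif (checked by substructure matching, not by
    construction flags) and ``p_ciat_no_motif`` otherwise.
    """
    if rng is None:
        rng = _substreams(config.seed)["truth"]
    p_m, p_0 = p_ciat if p_ciat is not None else (
        config.p_ciat_given_motif,
        config.p_ciat_no_motif,
    )
    if carriers is None:
        carriers = _motif_carriers(
            compounds, config.motif_smarts[: len(config.technologies)]
        )
    frames = []
    for tech, sm in zip(config.technologies, config.motif_smarts):
        has_motif = np.asarray(carriers[sm], dtype=bool)
        p = np.where(has_motif, p_m, p_0)
        is_ciat = rng.random(len(compounds)) < p
        frames.append(
            pd.DataFrame(
                {
                    "compound_id": compounds["compound_id"].to_numpy(),
                    "technology": tech,
                    "has_motif": has_motif,
                    "is_ciat": is_ciat,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _active_prob_miss(dist: Mapping[int, float], miss: float) -> float:
    """E over multiplicity k of (miss)^k, i.e. P(never active)."""
    return float(sum(p * (miss ** int(k)) for k, p in dist.items()))


def _calibration_scale(config: GeneratorConfig, carrier_frac: float) -> float:
    """Analytic scale on (p_m, p_0) so CIAT prevalence among actives hits target.

    prevalence = q·m_c / (q·m_c + (1-q)·m_n) with q the CIAT marginal,
    m_c / m_n the probabilities that a CIAT / non-CIAT is active in >=1
    artefact-linked primary.
    """
    t = config.target_ciat_prevalence
    assert t is not None
    h = config.base_hit_rate
    pen = config.ciat_primary_hit_rate
    m_n = 1.0 - _active_prob_miss(config.multiplicity_dist, 1.0 - h)
    m_c = 1.0 - _active_prob_miss(
        config.multiplicity_dist, (1.0 - pen) * (1.0 - h)
    )
    if m_c <= 0:
        raise CalibrationError("CIATs can never be primary-active; check penetrance")
    q_star = t * m_n / (m_c * (1.0 - t) + t * m_n)
    q0 = (
        carrier_frac * config.p_ciat_given_motif
        + (1.0 - carrier_frac) * config.p_ciat_no_motif
    )
    if q0 <= 0:
        raise CalibrationError("p_ciat_given_motif and p_ciat_no_motif are both 0")
    return q_star / q0


def _draw_multiplicity(
    dist: Mapping[int, float], n: int, rng: np.random.Generator
) -> np.ndarray:
    ks = np.array(sorted(int(k) for k in dist), dtype=int)
    ps = np.array([dist[k] for k in ks], dtype=float)
    ps = ps / ps.sum()
    return rng.choice(ks, size=n, p=ps)


def simulate_campaign(config: GeneratorConfig) -> SyntheticCampaign:
    """Simulate a full campaign: library, truth, assay results, artefacts.

    Primary flags: a compound is active in a primary assay if it is a true
    active there (``base_hit_rate``) or, for CIATs of that technology, if
    interference manifests (``ciat_primary_hit_rate``).  Most flags carry a
    Z-score source; a fraction get an additional, less reliable
    percent-effect flag, and a small fraction are inconclusive.  Every
    compound active in an artefact-linked primary receives a result in the
    linked artefact assay equal to the ground truth flipped with
    ``artefact_flip_noise``.

    When ``target_ciat_prevalence`` is set, the CIAT probabilities are
    rescaled so the realized CIAT fraction among primary actives lands
    within ``prevalence_tolerance`` of the target (bounded retries,
    :class:`CalibrationError` otherwise).
    """
    lib_rng = _substreams(config.seed)["library"]
    compounds = generate_library(config, lib_rng)
    motifs = list(config.motif_smarts[: len(config.technologies)])
    carriers = _motif_carriers(compounds, motifs)
    carrier_frac = float(np.mean([carriers[m] for m in motifs]))

    scale = 1.0
    if config.target_ciat_prevalence is not None:
        scale = _calibration_scale(config, carrier_frac)

    last_prev: dict[str, float] = {}
    for attempt in range(max(1, config.calibration_retries)):
        streams = _substreams(config.seed, attempt=attempt)
        p_m = min(1.0, config.p_ciat_given_motif * scale)
        p_0 = min(1.0, config.p_ciat_no_motif * scale)
        truth = assign_ground_truth(
            compounds, config, streams["truth"], p_ciat=(p_m, p_0), carriers=carriers
        )
        campaign = _realize_results(
            config, compounds, truth, streams["assignment"], streams["noise"]
        )
        campaign.calibrated_p_ciat = (p_m, p_0)
        if config.target_ciat_prevalence is None:
            return campaign
        last_prev = _realized_prevalence(campaign)
        target = config.target_ciat_prevalence
        if all(
            abs(p - target) <= config.prevalence_tolerance
            for p in last_prev.values()
        ):
            return campaign
        # nudge the scale toward the target in odds space and redraw
        mean_prev = float(np.mean(list(last_prev.values())))
        if 0.0 < mean_prev < 1.0 and 0.0 < target < 1.0:
            scale *= (target / (1 - target)) / (mean_prev / (1 - mean_prev))
    raise CalibrationError(
        "could not calibrate CIAT prevalence among primary actives to "
        f"{config.target_ciat_prevalence} +/- {config.prevalence_tolerance}; "
        f"achieved {last_prev}"
    )


def _realized_prevalence(campaign: SyntheticCampaign) -> dict[str, float]:
    """Ground-truth CIAT fraction among compounds active in >=1 linked primary."""
    out = {}
    res = campaign.results
    truth = campaign.ground_truth.set_index(["compound_id", "technology"])["is_ciat"]
    for tech in campaign.config.technologies:
        # artefact results are emitted exactly for reconciled primary actives
        mask = (res["technology"] == tech) & (res["assay_kind"] == "artefact")
        active_ids = res.loc[mask, "compound_id"].unique()
        if len(active_ids) == 0:
            out[tech] = float("nan")
            continue
        idx = pd.MultiIndex.from_product([active_ids, [tech]])
        out[tech] = float(truth.reindex(idx).fillna(False).mean())
    return out


def _realize_results(
    config: GeneratorConfig,
    compounds: pd.DataFrame,
    truth: pd.DataFrame,
    assign_rng: np.random.Generator,
    noise_rng: np.random.Generator,
) -> SyntheticCampaign:
    n = len(compounds)
    comp_ids = compounds["compound_id"].to_numpy()
    techs = list(config.technologies)
    truth_wide = truth.pivot(
        index="compound_id", columns="technology", values="is_ciat"
    ).reindex(comp_ids)

    assay_rows = []
    for tech in techs:
        for i in range(config.n_primary_assays):
            assay_rows.append(
                (f"{tech}-P{i + 1}", tech, "primary", f"{tech}-A{i + 1}")
            )
            assay_rows.append((f"{tech}-A{i + 1}", tech, "artefact", None))
        for i in range(config.n_extra_primary_assays):
            assay_rows.append((f"{tech}-X{i + 1}", tech, "primary", None))
    assays = pd.DataFrame(
        assay_rows,
        columns=["assay_id", "technology", "assay_kind", "linked_artefact_id"],
    )

    rec_comp: list[np.ndarray] = []
    rec_assay: list[np.ndarray] = []
    rec_tech: list[str] = []
    rec_kind: list[str] = []
    rec_flag: list[np.ndarray] = []
    rec_src: list[str] = []
    frames = []

    for tech in techs:
        is_ciat = truth_wide[tech].to_numpy(dtype=bool)
        linked_ids = np.array([f"{tech}-P{i + 1}" for i in range(config.n_primary_assays)])
        artefact_ids = np.array([f"{tech}-A{i + 1}" for i in range(config.n_primary_assays)])
        extra_ids = np.array(
            [f"{tech}-X{i + 1}" for i in range(config.n_extra_primary_assays)]
        )

        k_linked = _draw_multiplicity(config.multiplicity_dist, n, assign_rng)
        if config.n_extra_primary_assays > 0:
            k_extra = _draw_multiplicity(config.extra_multiplicity_dist, n, assign_rng)
        else:
            k_extra = np.zeros(n, dtype=int)

        rows = []
        for ci in range(n):
            chosen = assign_rng.choice(
                config.n_primary_assays, size=k_linked[ci], replace=False
            )
            for a in chosen:
                rows.append((ci, int(a), True))
            if k_extra[ci] > 0:
                chosen_x = assign_rng.choice(
                    config.n_extra_primary_assays, size=k_extra[ci], replace=False
                )
                for a in chosen_x:
                    rows.append((ci, int(a), False))
        idx = np.array([r[0] for r in rows], dtype=int)
        aidx = np.array([r[1] for r in rows], dtype=int)
        linked_mask = np.array([r[2] for r in rows], dtype=bool)

        true_active = noise_rng.random(len(rows)) < config.base_hit_rate
        interferes = (
            noise_rng.random(len(rows)) < config.ciat_primary_hit_rate
        ) & is_ciat[idx]
        active = true_active | interferes

        flags = np.where(active, _FLAG_ACTIVE, _FLAG_INACTIVE)
        inconclusive = noise_rng.random(len(rows)) < config.p_inconclusive
        zscore_flags = np.where(inconclusive, _FLAG_INCONCLUSIVE, flags)

        assay_names = np.where(linked_mask, linked_ids[aidx % max(len(linked_ids), 1)],
                               extra_ids[aidx % max(len(extra_ids), 1)] if len(extra_ids) else "")
        # (aidx is already within range for its pool; the modulo is a no-op guard)

        primary = pd.DataFrame(
            {
                "compound_id": comp_ids[idx],
                "assay_id": assay_names,
                "technology": tech,
                "assay_kind": "primary",
                "activity_flag": zscore_flags,
                "flag_source": "zscore",
            }
        )
        frames.append(primary)

        # secondary percent-effect flags: emitted for a fraction of rows, and
        # for half of the rows whose Z-score flag is inconclusive
        extra_flag = noise_rng.random(len(rows)) < config.p_extra_percent_flag
        rescue = inconclusive & (noise_rng.random(len(rows)) < 0.5)
        pe_mask = extra_flag | rescue
        pe_disagree = noise_rng.random(len(rows)) < 0.25
        pe_active = active ^ pe_disagree  # percent-effect flag, less reliable
        if pe_mask.any():
            percent = pd.DataFrame(
                {
                    "compound_id": comp_ids[idx[pe_mask]],
                    "assay_id": assay_names[pe_mask],
                    "technology": tech,
                    "assay_kind": "primary",
                    "activity_flag": np.where(
                        pe_active[pe_mask], _FLAG_ACTIVE, _FLAG_INACTIVE
                    ),
                    "flag_source": "percent_effect",
                }
            )
            frames.append(percent)

        # artefact results: one per (compound, linked primary) whose
        # reconciled primary flag is active -- the Z-score flag when
        # conclusive, otherwise the percent-effect fallback if present
        reconciled_active = np.where(
            inconclusive, pe_mask & pe_active, active
        ).astype(bool)
        art_mask = reconciled_active & linked_mask
        if art_mask.any():
            art_truth = is_ciat[idx[art_mask]]
            flips = noise_rng.random(int(art_mask.sum())) < config.artefact_flip_noise
            art_active = np.where(flips, ~art_truth, art_truth)
            artefact = pd.DataFrame(
                {
                    "compound_id": comp_ids[idx[art_mask]],
                    "assay_id": artefact_ids[aidx[art_mask]],
                    "technology": tech,
                    "assay_kind": "artefact",
                    "activity_flag": np.where(art_active, _FLAG_ACTIVE, _FLAG_INACTIVE),
                    "flag_source": "",
                }
            )
            frames.append(artefact)

    results = pd.concat(frames, ignore_index=True)
    results = results.sort_values(
        ["technology", "assay_id", "compound_id", "flag_source"], kind="mergesort"
    ).reset_index(drop=True)
    return SyntheticCampaign(
        config=config,
        compounds=compounds[["compound_id", "smiles"]].copy(),
        assays=assays,
        results=results,
        ground_truth=truth,
    )


def write_campaign(campaign: SyntheticCampaign, out_dir: str | Path) -> None:
    """Write a campaign as plain-text artifacts: CSVs plus a JSON truth map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    campaign.compounds.to_csv(out / "compounds.csv", index=False)
    campaign.assays.to_csv(out / "assays.csv", index=False)
    campaign.results.to_csv(out / "results.csv", index=False)
    (out / "ground_truth.json").write_text(
        json.dumps(campaign.ground_truth_map(), indent=0, sort_keys=True)
    )
    (out / "config.json").write_text(
        json.dumps(
            {
                "seed": campaign.config.seed,
                "n_compounds": campaign.config.n_compounds,
                "technologies": list(campaign.config.technologies),
                "calibrated_p_ciat": campaign.calibrated_p_ciat,
            },
            indent=2,
        )
    )


def read_campaign(in_dir: str | Path, config: GeneratorConfig | None = None) -> SyntheticCampaign:
    """Load a campaign previously written by :func:`write_campaign`."""
    p = Path(in_dir)
    compounds = pd.read_csv(p / "compounds.csv")
    assays = pd.read_csv(p / "assays.csv")
    # empty linked ids round-trip as NaN
    assays["linked_artefact_id"] = assays["linked_artefact_id"].where(
        assays["linked_artefact_id"].notna(), None
    )
    results = pd.read_csv(p / "results.csv", keep_default_na=False)
    truth_map = json.loads((p / "ground_truth.json").read_text())
    rows = [
        (cid, tech, label == "CIAT")
        for cid, per_tech in truth_map.items()
        for tech, label in per_tech.items()
    ]
    ground_truth = pd.DataFrame(
        rows, columns=["compound_id", "technology", "is_ciat"]
    )
    if config is None:
        meta = json.loads((p / "config.json").read_text())
        config = GeneratorConfig(
            n_compounds=meta["n_compounds"],
            technologies=tuple(meta["technologies"]),
            seed=meta["seed"],
        )
    return SyntheticCampaign(
        config=config,
        compounds=compounds,
        assays=assays,
        results=results,
        ground_truth=ground_truth,
    )
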
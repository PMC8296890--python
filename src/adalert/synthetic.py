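"""Synthetic drug-set generator with planted alert prevalences and odds ratios.

The generator emulates the statistical shape of a curated drug-safety
dataset — heavy class imbalance (50 AD-positive vs 357 AD-negative by
default), binary alert indicators drawn class-conditionally so each alert
carries a known (planted) odds ratio, a class-conditional high-dose flag,
and log-uniform daily doses partitioned at the 100 mg cutoff. Each drug's
SMILES is assembled from an inert alkane scaffold with the alert
substructures covalently attached exactly when the drawn indicator is
true, so re-screening the emitted structures reproduces the indicator
matrix bit-for-bit. The planted truth (odds ratios, expected contingency
tables, the indicator draw) is returned alongside the records, giving
every downstream stage a closed-form target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from rdkit import Chem
from scipy import stats

from .alerts import AlertLibrary, AlertPattern
from .association import ContingencyTable
from .errors import ConfigError
from .screening import ADLabel, DrugRecord

__all__ = [
    "PLANTED_FRAGMENTS",
    "SyntheticConfig",
    "PlantedTruth",
    "planted_odds_ratio",
    "generate_drug_set",
    "expected_contingency",
    "write_truth",
]

# alert_id -> (SMARTS that defines the alert, attachable SMILES fragment
# realizing it). Fragments bond to a scaffold carbon through their first
# atom; each must match its own SMARTS after attachment and no other
# pattern in the panel, which generation verifies.
PLANTED_FRAGMENTS: dict[str, tuple[str, str, str]] = {
    "aryl_amine_primary": (
        "[NX3;H2]c1ccccc1",
        "c1ccc(N)cc1",
        "benzene ring with nitrogen-containing substituent (two N-H bond)",
    ),
    "alkene": ("[CX3]=[CX3]", "C=C", "alkenes"),
    "alkyl_chloride": ("[CX4]Cl", "CCl", "halogenated carbon"),
    "phenol": ("[OX2H]c1ccccc1", "c1ccc(O)cc1", "benzene ring with hydroxyl group"),
}

_DEFAULT_PREVALENCE: dict[str, tuple[float, float]] = {
    # (P[alert | AD-positive], P[alert | AD-negative]) chosen to mirror the
    # headline screen: 14/50 vs 42/357 for the aromatic-amine alert, and
    # comparable frequencies for the companion motifs.
    "aryl_amine_primary": (0.28, 0.118),
    "alkene": (0.24, 0.143),
    "alkyl_chloride": (0.22, 0.179),
    "phenol": (0.12, 0.168),
}

_SCAFFOLDS = ("CCCCCC", "C1CCCCC1", "CCC(C)CC", "CC(C)CCC")


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic drug set.

    Defaults reproduce the reference screen's shape: 50 AD-positive and
    357 AD-negative drugs, high-dose prevalence 72% / 39.5% by class, and
    per-alert class-conditional prevalences planting odds ratios between
    ~0.7 and ~2.9. Doses are log-uniform on [1, 1000] mg, drawn above or
    below the 100 mg cutoff according to the high-dose indicator.
    """

    n_pos: int = 50
    n_neg: int = 357
    alert_prevalence: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_PREVALENCE)
    )
    p_highdose_pos: float = 0.72
    p_highdose_neg: float = 0.395
    dose_cutoff_mg: float = 100.0
    dose_range_mg: tuple[float, float] = (1.0, 1000.0)
    alert_correlation: float = 0.0  # Gaussian-copula rho between alerts; 0 = independent
    seed: int = 0
    scaffolds: tuple[str, ...] = _SCAFFOLDS

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ConfigError("n_pos and n_neg must each be >= 1")
        for aid, (p1, p0) in self.alert_prevalence.items():
            if not (0.0 <= p1 <= 1.0 and 0.0 <= p0 <= 1.0):
                raise ConfigError(f"alert {aid!r}: prevalences must lie in [0, 1]")
        for p in (self.p_highdose_pos, self.p_highdose_neg):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("high-dose prevalences must lie in [0, 1]")
        if not 0.0 <= self.alert_correlation < 1.0:
            raise ConfigError("alert_correlation must lie in [0, 1)")
        lo, hi = self.dose_range_mg
        if not (0 < lo < self.dose_cutoff_mg < hi):
            raise ConfigError(
                "dose_range_mg must bracket the cutoff: "
                f"{lo} < {self.dose_cutoff_mg} < {hi} violated"
            )

    @property
    def alert_ids(self) -> list[str]:
        return list(self.alert_prevalence)

    def alert_library(self) -> AlertLibrary:
        """The planted alerts as a screening library, in configuration order."""
        patterns = []
        for aid in self.alert_ids:
            if aid not in PLANTED_FRAGMENTS:
                raise ConfigError(f"no attachable fragment known for alert {aid!r}")
            smarts, _, desc = PLANTED_FRAGMENTS[aid]
            patterns.append(
                AlertPattern(alert_id=aid, smarts=smarts, description=desc, source="synthetic")
            )
        return AlertLibrary(patterns, name="synthetic-panel")


@dataclass
class PlantedTruth:
    """Ground truth accompanying one generated drug set."""

    alert_ids: list[str]
    planted_or: dict[str, float]
    expected_tables: dict[str, ContingencyTable]
    indicators: np.ndarray  # drugs x alerts, bool, generation order
    dose_high: np.ndarray  # drugs, bool
    labels: np.ndarray  # drugs, 1 = AD-positive
    cross_reactivity: dict[str, list[str]]
    config: SyntheticConfig


def planted_odds_ratio(p_pos: float, p_neg: float) -> float:
    """Population odds ratio implied by class-conditional prevalences."""
    if p_pos in (0.0, 1.0) or p_neg in (0.0, 1.0):
        return float("inf") if (p_pos > p_neg) else 0.0 if p_pos < p_neg else 1.0
    return (p_pos * (1.0 - p_neg)) / ((1.0 - p_pos) * p_neg)


def expected_contingency(config: SyntheticConfig, alert_id: str) -> ContingencyTable:
    """Expected (real-valued) 2x2 table for one alert at the configured n."""
    if alert_id not in config.alert_prevalence:
        raise ConfigError(f"alert {alert_id!r} is not configured")
    p1, p0 = config.alert_prevalence[alert_id]
    return ContingencyTable(
        tp=config.n_pos * p1,
        fn=config.n_pos * (1.0 - p1),
        fp=config.n_neg * p0,
        tn=config.n_neg * (1.0 - p0),
    )


def _check_fragments(config: SyntheticConfig) -> dict[str, list[str]]:
    """Verify each fragment realizes its own alert and report cross-matches."""
    queries = {}
    for aid in config.alert_ids:
        if aid not in PLANTED_FRAGMENTS:
            raise ConfigError(f"no attachable fragment known for alert {aid!r}")
        queries[aid] = Chem.MolFromSmarts(PLANTED_FRAGMENTS[aid][0])
    cross: dict[str, list[str]] = {}
    for aid in config.alert_ids:
        probe = Chem.MolFromSmiles(f"C({PLANTED_FRAGMENTS[aid][1]})C")
        if probe is None or not probe.HasSubstructMatch(queries[aid]):
            raise ConfigError(f"fragment for alert {aid!r} does not realize its pattern")
        hits = [
            other
            for other in config.alert_ids
            if other != aid and probe.HasSubstructMatch(queries[other])
        ]
        if hits:
            cross[aid] = hits
    return cross


def _draw_indicators(
    rng: np.random.Generator, n: int, probs: np.ndarray, rho: float
) -> np.ndarray:
    """Bernoulli draws per alert; optional exchangeable Gaussian-copula dependence."""
    k = len(probs)
    if rho == 0.0:
        return rng.random((n, k)) < probs
    z_common = rng.standard_normal((n, 1))
    z = np.sqrt(rho) * z_common + np.sqrt(1.0 - rho) * rng.standard_normal((n, k))
    return z < stats.norm.ppf(probs)


def _assemble_smiles(
    rng: np.random.Generator, config: SyntheticConfig, present: np.ndarray
) -> str:
    """Scaffold SMILES with one branch per planted alert fragment."""
    frags = [PLANTED_FRAGMENTS[aid][1] for aid, on in zip(config.alert_ids, present) if on]
    if not frags:
        return str(rng.choice(config.scaffolds))
    tail = "C" * int(rng.integers(0, 4))
    return "C" + "".join(f"({frag})C" for frag in frags) + tail


def generate_drug_set(config: SyntheticConfig) -> tuple[list[DrugRecord], PlantedTruth]:
    """Draw one synthetic drug set and its planted ground truth.

    Labels are fixed at ``n_pos``/``n_neg``; alert indicators and the
    high-dose flag are drawn class-conditionally and independently across
    drugs; doses are log-uniform within the side of the cutoff selected by
    the flag; SMILES realize the indicators by construction. The draw is a
    pure function of ``config`` (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    cross = _check_fragments(config)
    alert_ids = config.alert_ids
    p_pos = np.array([config.alert_prevalence[a][0] for a in alert_ids])
    p_neg = np.array([config.alert_prevalence[a][1] for a in alert_ids])

    labels = np.concatenate(
        [np.ones(config.n_pos, dtype=int), np.zeros(config.n_neg, dtype=int)]
    )
    ind_pos = _draw_indicators(rng, config.n_pos, p_pos, config.alert_correlation)
    ind_neg = _draw_indicators(rng, config.n_neg, p_neg, config.alert_correlation)
    indicators = np.vstack([ind_pos, ind_neg])
    dose_high = np.concatenate(
        [
            rng.random(config.n_pos) < config.p_highdose_pos,
            rng.random(config.n_neg) < config.p_highdose_neg,
        ]
    )

    lo, hi = config.dose_range_mg
    cut = config.dose_cutoff_mg
    u = rng.random(labels.size)
    log_lo, log_cut, log_hi = np.log(lo), np.log(cut), np.log(hi)
    doses = np.where(
        dose_high,
        np.exp(log_cut + u * (log_hi - log_cut)),
        np.exp(log_lo + u * (log_cut - log_lo)),
    )

    width = len(str(labels.size))
    drugs = [
        DrugRecord(
            drug_id=f"drug_{i + 1:0{width}d}",
            name=f"synthetic compound {i + 1}",
            smiles=_assemble_smiles(rng, config, indicators[i]),
            daily_dose_mg=float(np.round(doses[i], 3)),
            label=ADLabel.AD_POSITIVE if labels[i] else ADLabel.AD_NEGATIVE,
        )
        for i in range(labels.size)
    ]

    truth = PlantedTruth(
        alert_ids=alert_ids,
        planted_or={
            a: planted_odds_ratio(*config.alert_prevalence[a]) for a in alert_ids
        },
        expected_tables={a: expected_contingency(config, a) for a in alert_ids},
        indicators=indicators,
        dose_high=dose_high,
        labels=labels,
        cross_reactivity=cross,
        config=config,
    )
    return drugs, truth


def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    """Serialize the planted truth (config echo, ORs, expected tables) as JSON."""
    payload = {
        "config": {
            "n_pos": truth.config.n_pos,
            "n_neg": truth.config.n_neg,
            "alert_prevalence": truth.config.alert_prevalence,
            "p_highdose_pos": truth.config.p_highdose_pos,
            "p_highdose_neg": truth.config.p_highdose_neg,
            "dose_cutoff_mg": truth.config.dose_cutoff_mg,
            "alert_correlation": truth.config.alert_correlation,
            "seed": truth.config.seed,
        },
        "planted_or": truth.planted_or,
        "expected_tables": {
            a: {"tp": t.tp, "fn": t.fn, "fp": t.fp, "tn": t.tn}
            for a, t in truth.expected_tables.items()
        },
        "cross_reactivity": truth.cross_reactivity,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
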
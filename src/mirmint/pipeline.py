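"""End-to-end orchestration: counts + sequences -> negative-regulation pairs.

Thin glue over the stage modules, used by the command line, the acceptance
script and recovery tests.  The flow mirrors the analysis it simulates:
differential expression on both matrices, seed/energy target prediction,
then fold-change quadrant integration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Set, Tuple

import pandas as pd

from . import expression, integration, targets
from .synthetic_data import GeneratorConfig, TruthSet, design_for, generate_counts, \
    generate_mirnas, generate_utrs

__all__ = ["IntegrationResult", "integrate_study", "simulate_and_integrate"]


@dataclass
class IntegrationResult:
    mirna_de: pd.DataFrame
    mrna_de: pd.DataFrame
    target_pairs: List[targets.TargetPair]
    quadrant_pairs: List[integration.QuadrantPair]
    summary: integration.PairSummary

    @property
    def negative_pairs(self) -> List[integration.QuadrantPair]:
        return [p for p in self.quadrant_pairs if p.negative_regulation]


def integrate_study(
    mirna_counts: pd.DataFrame,
    mrna_counts: pd.DataFrame,
    design: Mapping[str, str],
    mirnas: Mapping[str, str],
    utrs: Mapping[str, str],
    alpha: float = 0.05,
    energy_max: float = -20.0,
    percentile_min: float = 90.0,
) -> IntegrationResult:
    """Differential expression -> target prediction -> quadrant analysis."""
    mirna_de = expression.call_differential(
        expression.ExpressionMatrix(mirna_counts, design), alpha=alpha
    )
    mrna_de = expression.call_differential(
        expression.ExpressionMatrix(mrna_counts, design), alpha=alpha
    )
    panel = [targets.MatureMiRNA(mid, seq) for mid, seq in sorted(mirnas.items())]
    pairs = targets.predict_targets(
        panel, dict(utrs), energy_max=energy_max, percentile_min=percentile_min
    )
    quadrant_pairs = integration.correlate(pairs, mirna_de, mrna_de)
    return IntegrationResult(
        mirna_de=mirna_de,
        mrna_de=mrna_de,
        target_pairs=pairs,
        quadrant_pairs=quadrant_pairs,
        summary=integration.summarize_pairs(quadrant_pairs),
    )


def simulate_and_integrate(
    config: GeneratorConfig,
) -> Tuple[IntegrationResult, TruthSet]:
    """One simulated study pushed through the full integration pipeline."""
    mirna_counts, mrna_counts, truth = generate_counts(config)
    mirnas = generate_mirnas(config)
    utrs, truth = generate_utrs(config, truth, mirnas)
    result = integrate_study(
        mirna_counts, mrna_counts, design_for(config), mirnas, utrs
    )
    return result, truth
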
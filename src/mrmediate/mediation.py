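"""Two-step MR mediation: product-of-coefficients decomposition.

For an exposure E (microbial taxon), candidate mediator X (blood
metabolite) and outcome O (disease), three MR estimates feed the
decomposition: beta0 (E→O, the total effect), beta1 (E→X) and beta2
(X→O).  The mediated effect is b = beta1·beta2, the direct effect is
beta0 − b, and the mediated proportion is b/beta0.  A mediator whose
indirect effect shares the total effect's sign is a positive mediator
(strengthens the pathway); an opposing sign marks a negative mediator
(weakens or reverses it).  The se of b uses the delta method,
sqrt(beta1²·se2² + beta2²·se1²) — an uncertainty statement beyond the
bare decomposition, clearly labelled as such.

The network assembly walks three screens' verdicts and emits one
mediation triplet for every (E, X) with all three links significant,
plus metabolite-independent direct nodes for exposures whose effect on
the outcome has no significant mediator link.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .pipeline import AnalysisVerdict

__all__ = [
    "MediationResult",
    "MediationNetwork",
    "mediation_effect",
    "build_mediation_network",
]


@dataclass(frozen=True)
class MediationResult:
    """Total/indirect/direct decomposition for one E→X→O triplet."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta0: float
    beta1: float
    beta2: float
    b: float
    direct: float
    proportion: float | None
    classification: str  # positive_mediator | negative_mediator
    se_b: float

    def as_row(self) -> dict:
        return {
            "exposure": self.exposure_id,
            "mediator": self.mediator_id,
            "outcome": self.outcome_id,
            "beta0": self.beta0,
            "beta1": self.beta1,
            "beta2": self.beta2,
            "b": self.b,
            "direct": self.direct,
            "proportion": np.nan if self.proportion is None else self.proportion,
            "classification": self.classification,
            "se_b": self.se_b,
        }


def mediation_effect(
    beta0: float,
    beta1: float,
    beta2: float,
    se1: float,
    se2: float,
    exposure_id: str = "exposure",
    mediator_id: str = "mediator",
    outcome_id: str = "outcome",
) -> MediationResult:
    """Product-of-coefficients mediation for one triplet.

    b = beta1·beta2, direct = beta0 − b (so b + direct = beta0 exactly);
    the mediated proportion b/beta0 is undefined (None) when beta0 = 0.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    # NaN ses (e.g. a skipped bootstrap) are allowed and propagate into se_b
    b = beta1 * beta2
    direct = beta0 - b
    proportion = b / beta0 if beta0 != 0 else None
    classification = "positive_mediator" if math.copysign(1.0, b) == math.copysign(1.0, beta0) else "negative_mediator"
    se_b = math.sqrt(beta1**2 * se2**2 + beta2**2 * se1**2)
    return MediationResult(exposure_id, mediator_id, outcome_id,
                           beta0, beta1, beta2, b, direct, proportion, classification, se_b)


@dataclass
class MediationNetwork:
    """Edge list of the exposure-mediator-outcome network.

    Edge types: ``exposure->mediator``, ``mediator->outcome`` and
    ``exposure->outcome_direct``; node kinds are implied by position.
    Suitable as-is for any Sankey renderer.
    """

    edges: pd.DataFrame

    COLUMNS = ("source", "target", "value", "edge_type")

    def to_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False, float_format="%.10g")


def build_mediation_network(
    micro_gbm: Sequence[AnalysisVerdict],
    metab_gbm: Sequence[AnalysisVerdict],
    micro_metab: Sequence[AnalysisVerdict],
) -> tuple[MediationNetwork, list[MediationResult]]:
    """Assemble mediation triplets from the three screens' verdicts.

    A triplet (E, X, O) is emitted when E→O, E→X and X→O are all
    significant; beta0 comes from the E→O primary estimate, beta1 from
    E→X and beta2 from X→O (each screen's decision-rule estimator).
    Exposures significant for the outcome without any significant mediator
    link contribute a single direct edge.  Empty screens yield an empty
    network, not an error.
    """
    metab_sig = {v.exposure_id: v for v in metab_gbm if v.significant}
    link_sig: dict[str, list[AnalysisVerdict]] = {}
    for v in micro_metab:
        if v.significant and v.outcome_id in metab_sig:
            link_sig.setdefault(v.exposure_id, []).append(v)

    results: list[MediationResult] = []
    edge_rows: list[dict] = []
    for v0 in micro_gbm:
        if not v0.significant:
            continue
        exposure, outcome = v0.exposure_id, v0.outcome_id
        links = link_sig.get(exposure, [])
        if not links:
            edge_rows.append({"source": exposure, "target": outcome,
                              "value": v0.primary_result.beta_hat, "edge_type": "exposure->outcome_direct"})
            continue
        for v1 in links:
            v2 = metab_sig[v1.outcome_id]
            med = mediation_effect(
                beta0=v0.primary_result.beta_hat,
                beta1=v1.primary_result.beta_hat,
                beta2=v2.primary_result.beta_hat,
                se1=v1.primary_result.se_hat,
                se2=v2.primary_result.se_hat,
                exposure_id=exposure,
                mediator_id=v1.outcome_id,
                outcome_id=outcome,
            )
            results.append(med)
            edge_rows.append({"source": exposure, "target": med.mediator_id,
                              "value": med.beta1, "edge_type": "exposure->mediator"})
            edge_rows.append({"source": med.mediator_id, "target": outcome,
                              "value": med.beta2, "edge_type": "mediator->outcome"})
            edge_rows.append({"source": exposure, "target": outcome,
                              "value": med.direct, "edge_type": "exposure->outcome_direct"})
    edges = pd.DataFrame(edge_rows, columns=list(MediationNetwork.COLUMNS)).drop_duplicates().reset_index(drop=True)
    return MediationNetwork(edges), results


def mediation_table(results: Sequence[MediationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in results])
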
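"""Hill-equation channel pharmacology.

Inhibitors follow a simple pore-block model: at drug concentration ``D``
the channel conductance is multiplied by ``1/(1 + (D/IC50)^h)``.  Agonists
multiply the conductance by ``1 + A_max * D^h/(D^h + EC50^h)``, a saturable
enhancement.  Drug action is purely multiplicative on maximal
conductances/currents; gating kinetics are untouched.

Per-drug channel tables ship as CSV data (``cardiomech/data/drugs.csv``)
so the half-maximal concentrations and Hill coefficients are auditable and
replaceable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

from .parameters import CHANNELS, IonicParameters, apply_channel_scaling

__all__ = ["DrugAction", "DrugSpec", "block_multiplier",
           "agonist_multiplier", "apply_drug", "load_drug_table"]


def block_multiplier(D: float, IC50: float, h: float) -> float:
    """Pore-block conductance factor in (0, 1] at concentration ``D``.

    ``D`` and ``IC50`` share any concentration unit; ``h`` is the Hill
    coefficient.  ``D = 0`` gives 1 (no block); ``D = IC50`` gives 0.5.
    """
    if D < 0:
        raise ValueError("concentration must be >= 0")
    if IC50 <= 0 or h <= 0:
        raise ValueError("IC50 and Hill coefficient must be > 0")
    return 1.0 / (1.0 + (D / IC50) ** h)


def agonist_multiplier(D: float, EC50: float, h: float, A_max: float) -> float:
    """Saturable enhancement factor >= 1 at concentration ``D``.

    ``A_max`` is the maximal fractional enhancement: the factor tends to
    ``1 + A_max`` at saturating concentration and is ``1 + A_max/2`` at
    ``D = EC50``.
    """
    if D < 0:
        raise ValueError("concentration must be >= 0")
    if EC50 <= 0 or h <= 0:
        raise ValueError("EC50 and Hill coefficient must be > 0")
    if A_max < 0:
        raise ValueError("A_max must be >= 0")
    if D == 0.0:
        return 1.0
    occ = D ** h / (D ** h + EC50 ** h)
    return 1.0 + A_max * occ


@dataclass
class DrugAction:
    """One channel's response to a drug."""

    channel: str                # e.g. "I_CaL"
    half_max_nM: float          # IC50 (block) or EC50 (agonist)
    hill: float
    mode: str = "block"         # "block" | "agonist"
    a_max: float = 0.0          # agonist maximal enhancement

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise KeyError(f"unknown channel {self.channel!r}")
        if self.half_max_nM <= 0 or self.hill <= 0:
            raise ValueError("half-max concentration and Hill must be > 0")
        if self.mode not in ("block", "agonist"):
            raise ValueError(f"mode must be 'block' or 'agonist', got {self.mode!r}")

    def multiplier(self, D_nM: float) -> float:
        if self.mode == "block":
            return block_multiplier(D_nM, self.half_max_nM, self.hill)
        return agonist_multiplier(D_nM, self.half_max_nM, self.hill,
                                  self.a_max)


@dataclass
class DrugSpec:
    """A named compound acting on one or more channels."""

    name: str
    actions: list[DrugAction] = field(default_factory=list)

    def multipliers(self, D_nM: float) -> dict[str, float]:
        return {a.channel: a.multiplier(D_nM) for a in self.actions}


def apply_drug(params: IonicParameters, drug: DrugSpec,
               D_nM: float) -> IonicParameters:
    """Scale channel multipliers by the drug's Hill factors at ``D_nM``.

    Composes with any multipliers already present on ``params``.
    """
    return apply_channel_scaling(params, drug.multipliers(D_nM))


def load_drug_table(path=None) -> dict[str, DrugSpec]:
    """Load a drug table CSV (columns drug,channel,half_max_nM,hill,mode,a_max).

    Without ``path``, the packaged table is used.
    """
    if path is None:
        text = (resources.files("cardiomech") / "data" / "drugs.csv").read_text()
    else:
        with open(path, newline="") as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if not ln.lstrip().startswith("#")]
    rows = list(csv.DictReader(lines))
    drugs: dict[str, DrugSpec] = {}
    for row in rows:
        name = row["drug"].strip()
        spec = drugs.setdefault(name, DrugSpec(name=name))
        spec.actions.append(DrugAction(
            channel=row["channel"].strip(),
            half_max_nM=float(row["half_max_nM"]),
            hill=float(row["hill"]),
            mode=row["mode"].strip(),
            a_max=float(row.get("a_max") or 0.0),
        ))
    return drugs
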
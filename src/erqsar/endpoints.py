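"""Modeling endpoints: pIC50 per receptor subtype and the selectivity index S.

The selectivity statistic quantifies how much more strongly a ligand binds
the beta subtype than the alpha subtype,

    S = log10((IC50_alpha - IC50_beta) / IC50_beta)
      = log10(10**(pIC50_beta - pIC50_alpha) - 1),

defined only when IC50_alpha > IC50_beta (i.e. pIC50_beta > pIC50_alpha).
S grows monotonically with the affinity gap and is invariant to shifting
both pIC50 values by the same constant.  At S = 1 the IC50 ratio is 11
(the literal algebra; see docs/methods.md for the "10-fold" prose nuance).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .dataset import CompoundTable
from .errors import DomainError, UsageError

__all__ = ["EndpointTable", "compute_S", "build_endpoint_table", "round_half_away"]

Endpoint = Literal["alpha", "beta", "selectivity"]


@dataclass
class EndpointTable:
    """Response vector for one modeling endpoint, aligned to compound ids."""

    endpoint: Endpoint
    compound_ids: list[str]
    y: np.ndarray

    def __len__(self) -> int:
        return len(self.compound_ids)


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention matching the printed table)."""
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def compute_S(pic50_alpha: float, pic50_beta: float) -> float | None:
    """Selectivity index from the two subtype pIC50 values.

    Returns ``None`` ("undefined") when the ligand does not bind the beta
    subtype more strongly; the study excludes such compounds rather than
    assigning a sentinel value.
    """
    if not (math.isfinite(pic50_alpha) and math.isfinite(pic50_beta)):
        raise DomainError("pIC50 inputs must be finite")
    delta = pic50_beta - pic50_alpha
    if delta <= 0:
        return None
    return math.log10(10.0**delta - 1.0)


def build_endpoint_table(table: CompoundTable, endpoint: Endpoint) -> EndpointTable:
    """Assemble the response vector for one endpoint.

    The alpha/beta tables carry every compound; the selectivity table keeps
    only compounds with a defined S (81 of the 82 fixture ligands), in the
    original order.
    """
    if endpoint in ("alpha", "beta"):
        ids = table.compound_ids
        y = np.array(
            [r.pic50_alpha if endpoint == "alpha" else r.pic50_beta for r in table],
            dtype=float,
        )
    elif endpoint == "selectivity":
        ids, vals = [], []
        for rec in table:
            s = compute_S(rec.pic50_alpha, rec.pic50_beta)
            if s is not None:
                ids.append(rec.compound_id)
                vals.append(s)
        y = np.array(vals, dtype=float)
    else:
        raise UsageError(f"unknown endpoint {endpoint!r}")
    return EndpointTable(endpoint=endpoint, compound_ids=ids, y=y)
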
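"""Pairwise conditional models and forward-stepwise cell-type selection.

A significant cell type can owe its signal to a transcriptomically similar
neighbour. The conditional model refits the gene-property regression with
two specificity columns at once; *proportional significance*

    PS(c1 | c2) = -log P(c1 | c2) / -log P(c1)

measures how much of c1's marginal significance survives conditioning on
c2. Forward-stepwise selection keeps the "relatively independent"
significant cell types: starting from the most marginally significant,
each next candidate joins the selected set only if, against every member,
either both PS values are >= 0.8 (independent) or both lie in [0.5, 0.8)
with the candidate's conditional P <= 0.05 (partially independent). When
an established member loses its signal against a candidate
(PS(member | candidate) < 0.2 <= PS(candidate | member)) the roles are
reversed: the member is excluded as explained and the candidate takes its
place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .gene_assoc import PVALUE_FLOOR
from .regression import CollinearityError, ScanEngine

PS_INDEPENDENT = 0.8
PS_PARTIAL = 0.5
PS_REVERSAL = 0.2
RULE2_P_THRESHOLD = 0.05

STATUS_INDEPENDENT = "selected_independent"
STATUS_PARTIAL = "selected_partial"
STATUS_EXPLAINED = "excluded_explained"
STATUS_NOT_SIG = "not_significant"


@dataclass
class ConditionalPair:
    c1: object
    c2: object
    p_c1_given_c2: float
    p_c2_given_c1: float
    ps_c1_c2: float
    ps_c2_c1: float


@dataclass
class SelectionResult:
    selected: list = field(default_factory=list)
    status: dict = field(default_factory=dict)
    audit: pd.DataFrame = field(default_factory=pd.DataFrame)


def proportional_significance(p_conditional: float, p_marginal: float) -> float:
    """Ratio of negative log p-values (base-invariant); in [0, inf)."""
    if not (0.0 < p_conditional <= 1.0):
        raise ValueError("conditional P must lie in (0, 1]")
    if not (0.0 < p_marginal < 1.0):
        raise ValueError("marginal P must lie in (0, 1) for PS to be defined")
    return math.log(p_conditional) / math.log(p_marginal)


def conditional_fit(
    engine: ScanEngine,
    c1,
    c2,
    p_marg1: float,
    p_marg2: float,
) -> ConditionalPair:
    """Two-cell-type GLS fit; one-sided P for both slopes plus PS values.

    Specificity columns enter with the same truncation as the marginal
    scan. Near-duplicate columns (|corr| > 0.9999) raise CollinearityError
    and the pair is reported "indistinguishable" by the selection step.
    """
    if c1 == c2:
        raise ValueError("conditional model needs two distinct cell types")
    i1 = engine.celltypes.index(c1)
    i2 = engine.celltypes.index(c2)
    s1 = engine.spec_truncated[:, i1]
    s2 = engine.spec_truncated[:, i2]
    if abs(np.corrcoef(s1, s2)[0, 1]) > 0.9999:
        raise CollinearityError(f"specificity[{c1}] vs specificity[{c2}]: indistinguishable")

    zw = linalg.solve_triangular(engine.L, engine.Z, lower=True)
    Xw = np.column_stack([engine.base_w, engine.Sw[:, i1], engine.Sw[:, i2]])
    beta, _, rank, _ = np.linalg.lstsq(Xw, zw, rcond=None)
    if rank < Xw.shape[1]:
        raise CollinearityError(f"conditional design for ({c1}, {c2})")
    resid = zw - Xw @ beta
    df = len(zw) - Xw.shape[1]
    sigma2 = float(resid @ resid) / df
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    ps = []
    pcond = []
    for j, p_marg in ((Xw.shape[1] - 2, p_marg1), (Xw.shape[1] - 1, p_marg2)):
        se = math.sqrt(max(sigma2 * XtX_inv[j, j], 0.0))
        if se == 0.0:
            p = PVALUE_FLOOR if beta[j] > 0 else 1.0
        else:
            p = float(np.clip(stats.t.sf(beta[j] / se, df), PVALUE_FLOOR, 1.0))
        pcond.append(p)
        ps.append(proportional_significance(p, p_marg))
    return ConditionalPair(c1, c2, pcond[0], pcond[1], ps[0], ps[1])


def forward_stepwise(
    scan: pd.DataFrame,
    engine: ScanEngine | None = None,
    pair_fn=None,
    rule2_use_conditional: bool = True,
    ps_independent: float = PS_INDEPENDENT,
    ps_partial: float = PS_PARTIAL,
    ps_reversal: float = PS_REVERSAL,
    rule2_p: float = RULE2_P_THRESHOLD,
) -> SelectionResult:
    """Forward-stepwise selection of relatively independent cell types.

    ``scan`` is the marginal scan table (CELLTYPE, P_ONESIDED, BONF_SIG).
    Pairwise conditional fits come from ``pair_fn(c1, c2, p1, p2)`` (by
    default :func:`conditional_fit` on ``engine``). Every pairwise
    comparison and the rule it fired are recorded in the audit table.
    """
    if pair_fn is None:
        if engine is None:
            raise ValueError("provide either a ScanEngine or a pair_fn")
        marg = dict(zip(scan["CELLTYPE"], scan["P_ONESIDED"]))

        def pair_fn(c1, c2):
            return conditional_fit(engine, c1, c2, marg[c1], marg[c2])

    status = {c: STATUS_NOT_SIG for c in scan["CELLTYPE"]}
    audit_rows: list[dict] = []
    sig = scan[scan["BONF_SIG"]].sort_values(
        ["P_ONESIDED", "CELLTYPE"], kind="mergesort"
    )
    if sig.empty:
        return SelectionResult([], status, pd.DataFrame(audit_rows))

    order = list(sig["CELLTYPE"])
    selected: list = [order[0]]
    used_partial: set = set()
    status[order[0]] = STATUS_INDEPENDENT

    for c in order[1:]:
        accept = True
        partial = False
        for s in list(selected):
            try:
                pair = pair_fn(c, s)
            except CollinearityError:
                audit_rows.append(
                    {"C1": c, "C2": s, "P_COND_12": np.nan, "P_COND_21": np.nan,
                     "PS_12": np.nan, "PS_21": np.nan, "RULE_FIRED": "collinear"}
                )
                accept = False
                break
            ps_cs, ps_sc = pair.ps_c1_c2, pair.ps_c2_c1
            row = {
                "C1": c, "C2": s,
                "P_COND_12": pair.p_c1_given_c2, "P_COND_21": pair.p_c2_given_c1,
                "PS_12": ps_cs, "PS_21": ps_sc,
            }
            # s entered first (smaller marginal P); if it loses its signal
            # against c while c keeps its own, the selection order reverses.
            if ps_sc < ps_reversal <= ps_cs:
                row["RULE_FIRED"] = "reversal"
                audit_rows.append(row)
                selected.remove(s)
                status[s] = STATUS_EXPLAINED
                continue
            if ps_cs >= ps_independent and ps_sc >= ps_independent:
                row["RULE_FIRED"] = "independent"
                audit_rows.append(row)
                continue
            p_rule2 = pair.p_c1_given_c2 if rule2_use_conditional else float(
                scan.loc[scan["CELLTYPE"] == c, "P_ONESIDED"].iloc[0]
            )
            if (
                ps_partial <= ps_cs < ps_independent
                and ps_partial <= ps_sc < ps_independent
                and p_rule2 <= rule2_p
            ):
                row["RULE_FIRED"] = "partial"
                audit_rows.append(row)
                partial = True
                continue
            row["RULE_FIRED"] = "fail"
            audit_rows.append(row)
            accept = False
            break
        if accept:
            selected.append(c)
            if partial:
                used_partial.add(c)
            status[c] = STATUS_PARTIAL if partial else STATUS_INDEPENDENT
        else:
            status[c] = STATUS_EXPLAINED

    audit = pd.DataFrame(
        audit_rows,
        columns=["C1", "C2", "P_COND_12", "P_COND_21", "PS_12", "PS_21", "RULE_FIRED"],
    )
    return SelectionResult(selected, status, audit)
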
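"""qPCR validation: relative enrichment (RE), t-tests and ER-RE concordance.

RE for a target is the ratio of the amount of its sequence in the antibody
fraction to the amount in the mock (no-antibody) fraction, with amounts
reconstructed from Ct values under the exponential amplification model
amount ∝ (1+E)^(-Ct).  Replicates are paired index-wise (replicate i antibody
over replicate i mock), since each independent ChIP reaction yields a matched
antibody/mock pair; an unpaired mean-ratio mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .simulate import QPCRPlate


@dataclass
class REResult:
    target_id: str
    re: float
    replicate_res: list[float]
    control_id: str | None = None
    t_statistic: float | None = None
    p_value: float | None = None
    degenerate: bool = False


@dataclass
class ConcordanceResult:
    pairs: list[tuple[str, float, float]]  # (target_id, er, re)
    r: float
    undefined: bool = False
    unmatched: list[str] = field(default_factory=list)


def _cts(plate: QPCRPlate, target_id: str, fraction: str) -> np.ndarray:
    t = plate.table
    sel = t[(t.target_id == target_id) & (t.fraction == fraction)]
    if sel.empty:
        raise ValueError(f"no {fraction} wells for target {target_id!r}")
    return sel.sort_values("replicate")["ct"].to_numpy()


def compute_re(
    plate: QPCRPlate,
    target_id: str,
    efficiency: float | None = None,
    paired: bool = True,
) -> REResult:
    """Per-replicate and mean RE for one target.

    amount_i ∝ (1+E)^(-ct_i); re_i = amount_antibody_i / amount_mock_i.  The
    unknown proportionality constant cancels in the ratio.
    """
    eff = plate.efficiency if efficiency is None else efficiency
    if eff <= 0:
        raise ValueError("efficiency must be positive")
    ab = _cts(plate, target_id, "antibody")
    mock = _cts(plate, target_id, "mock")
    if len(ab) != len(mock):
        raise ValueError("antibody and mock replicate counts differ")
    base = 1.0 + eff
    if paired:
        res = (base ** (mock - ab)).tolist()
    else:
        amounts_ab = base ** (-ab)
        amounts_mock = base ** (-mock)
        res = [float(amounts_ab.mean() / amounts_mock.mean())] * len(ab)
    return REResult(target_id, float(np.mean(res)), [float(x) for x in res])


def test_vs_control(target_res: list[float], control_res: list[float]) -> tuple[float, float]:
    """Two-sample, two-tailed, equal-variance Student's t on replicate REs."""
    a = np.asarray(target_res, dtype=float)
    b = np.asarray(control_res, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 replicates")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ZeroDivisionError("zero variance with unequal means: t undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def validate_targets(
    plate: QPCRPlate,
    target_ids: list[str],
    control_id: str,
    efficiency: float | None = None,
    paired: bool = True,
) -> list[REResult]:
    """RE for every target plus a t-test of its replicate REs against the control's."""
    control = compute_re(plate, control_id, efficiency, paired)
    out = []
    for tid in target_ids:
        r = compute_re(plate, tid, efficiency, paired)
        r.control_id = control_id
        try:
            r.t_statistic, r.p_value = test_vs_control(r.replicate_res, control.replicate_res)
        except ZeroDivisionError:
            r.degenerate = True
        out.append(r)
    return out


def correlate_er_re(
    er_table: dict[str, float],
    re_table: dict[str, float],
) -> ConcordanceResult:
    """Pearson product-moment r over targets present in both tables."""
    shared = sorted(set(er_table) & set(re_table))
    unmatched = sorted(set(er_table) ^ set(re_table))
    pairs = [(t, er_table[t], re_table[t]) for t in shared]
    if len(pairs) < 3:
        return ConcordanceResult(pairs, float("nan"), undefined=True, unmatched=unmatched)
    ers = np.array([p[1] for p in pairs])
    res = np.array([p[2] for p in pairs])
    if ers.std() == 0 or res.std() == 0:
        return ConcordanceResult(pairs, float("nan"), undefined=True, unmatched=unmatched)
    r, _ = stats.pearsonr(ers, res)
    return ConcordanceResult(pairs, float(r), unmatched=unmatched)
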
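"""Two-group comparison of per-sample proximity fractions.

The group contrast (e.g. control vs diseased, n = 7 vs n = 5) is tested per
query distance with an unpaired two-tailed Student's t-test — the pooled
(equal-variance) form, since that is what the name denotes; Welch's form is
available behind a flag.  No multiple-testing correction is applied across
the query distances; the report footer says so.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConsistencyError, SampleSizeError
from .morphometry import ProximityProfile

__all__ = ["GroupComparison", "student_t_test", "summarize_groups"]

NO_CORRECTION_NOTE = (
    "p-values are per query distance with no multiple-testing correction"
)


@dataclass(frozen=True)
class GroupComparison:
    """Result of one two-group test at one query distance."""

    query_distance_um: float
    label_a: str
    label_b: str
    values_a: tuple[float, ...]
    values_b: tuple[float, ...]
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    t_statistic: float
    degrees_of_freedom: float
    p_value: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["values_a"] = list(d["values_a"])
        d["values_b"] = list(d["values_b"])
        return d


def student_t_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    *,
    labels: tuple[str, str] = ("a", "b"),
    query_distance_um: float = float("nan"),
    welch: bool = False,
) -> GroupComparison:
    """Unpaired two-tailed t-test; pooled variance by default, Welch optional.

    The t sign follows ``mean_a - mean_b``.  If both groups are constant and
    equal, ``t = 0`` and ``p = 1`` by convention, with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise SampleSizeError(
            f"need >= 2 samples per group, got {a.size} and {b.size}"
        )
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    if welch:
        se2 = va / na + vb / nb
        df = (
            se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
            if se2 > 0 else float(na + nb - 2)
        )
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
        df = float(na + nb - 2)
    if se2 == 0:
        if ma == mb:
            warnings.warn(
                "both groups constant and equal: t = 0, p = 1 by convention",
                stacklevel=2,
            )
            t, p = 0.0, 1.0
        else:
            t = math.copysign(math.inf, ma - mb)
            p = 0.0
    else:
        t = (ma - mb) / math.sqrt(se2)
        p = 2.0 * float(sps.t.sf(abs(t), df))
    return GroupComparison(
        query_distance_um=float(query_distance_um),
        label_a=labels[0], label_b=labels[1],
        values_a=tuple(a), values_b=tuple(b),
        mean_a=float(ma), mean_b=float(mb),
        sd_a=float(math.sqrt(va)), sd_b=float(math.sqrt(vb)),
        n_a=int(na), n_b=int(nb),
        t_statistic=float(t), degrees_of_freedom=float(df),
        p_value=float(min(p, 1.0)),
    )


def summarize_groups(
    profiles: Sequence[ProximityProfile],
    group_map: Mapping[str, str],
    query_distances_um: Sequence[float],
    *,
    welch: bool = False,
) -> tuple[pd.DataFrame, list[GroupComparison]]:
    """Per-sample table plus one :class:`GroupComparison` per query distance.

    Every profile must be assigned to exactly one of two groups and carry an
    evaluation at every query distance; the per-sample fractions are echoed
    into the table unmodified.
    """
    problems = []
    for p in profiles:
        if p.sample_name not in group_map:
            problems.append(f"sample {p.sample_name!r} has no group assignment")
    labels = sorted(set(group_map[p.sample_name] for p in profiles
                        if p.sample_name in group_map))
    if len(labels) != 2:
        problems.append(f"need exactly 2 groups, got {labels}")
    for p in profiles:
        for d in query_distances_um:
            if float(d) not in p.evaluations:
                problems.append(
                    f"sample {p.sample_name!r} has no evaluation at {d} um"
                )
    if problems:
        raise ConsistencyError("; ".join(problems))

    rows = []
    for p in profiles:
        row = p.csv_row()
        row["group"] = group_map[p.sample_name]
        rows.append(row)
    table = pd.DataFrame(rows)
    cols = ["sample", "group", "n_organ_voxels"]
    table = table[cols + [c for c in table.columns if c not in cols]]

    comparisons = []
    for d in query_distances_um:
        by_label = {
            lab: [p.fraction_within(d) for p in profiles
                  if group_map[p.sample_name] == lab]
            for lab in labels
        }
        comparisons.append(
            student_t_test(
                by_label[labels[0]], by_label[labels[1]],
                labels=(labels[0], labels[1]),
                query_distance_um=float(d), welch=welch,
            )
        )
    return table, comparisons
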
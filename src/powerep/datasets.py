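"""Built-in example data: the "Labels" replication experiment.

A standardized-mean-difference original study (estimate 0.21, SE 0.05,
n = 1577) that was replicated by three external laboratories.  The first
replication found a smaller effect, the second an identical one, and the
third a larger one — together they exercise the full range of
compatibility outcomes.
"""

from __future__ import annotations

from .models import ReplicationPair, StudySummary

LABELS_ORIGINAL = StudySummary(0.21, 0.05, "Labels original")

LABELS_REPLICATIONS = (
    StudySummary(0.09, 0.05, "Labels replication 1"),
    StudySummary(0.21, 0.06, "Labels replication 2"),
    StudySummary(0.44, 0.04, "Labels replication 3"),
)


def labels_pair(replication: int) -> ReplicationPair:
    """The Labels original paired with replication 1, 2 or 3."""
    if replication not in (1, 2, 3):
        raise ValueError("replication must be 1, 2 or 3")
    return ReplicationPair(LABELS_ORIGINAL, LABELS_REPLICATIONS[replication - 1])
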
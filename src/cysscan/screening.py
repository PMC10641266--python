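"""Initial biophysical screen: candidate retention.

After panning, enriched Cys pairs are introduced into a small panel of
canonical-disulfide-bearing domains and their melting temperatures compared
to wild type.  A pair is retained for full characterisation when at least
one screened domain both expressed and showed a Tm increase; pairs that
fail to express or lose Tm in every domain are dropped.
"""

from __future__ import annotations

import math

import pandas as pd

__all__ = ["retain_candidates"]

Pair = tuple[int, int]


def retain_candidates(screen: dict[Pair, dict[str, float | None]]
                      ) -> list[Pair]:
    """Apply the initial-screen retention rule.

    ``screen`` maps each candidate pair to {domain id: delta-Tm in degrees C,
    or None for a domain that failed to express}.  A pair is retained iff
    any domain has a finite delta-Tm > 0.  Returned pairs are sorted.
    """
    retained: list[Pair] = []
    for pair, deltas in screen.items():
        if any(d is not None and math.isfinite(d) and d > 0
               for d in deltas.values()):
            retained.append(tuple(sorted(pair)))
    return sorted(retained)


def screen_to_frame(screen: dict[Pair, dict[str, float | None]]) -> pd.DataFrame:
    rows = []
    for pair, deltas in sorted(screen.items()):
        for domain, d in sorted(deltas.items()):
            rows.append({"p1": pair[0], "p2": pair[1], "domain": domain,
                         "delta_tm": d})
    return pd.DataFrame(rows)
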
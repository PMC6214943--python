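"""Run-wide configuration and logging setup.

All tunable knobs of the pipeline live in :class:`RunConfig` so that a run can
be echoed to JSON alongside its outputs and reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass

logger = logging.getLogger("isoresolve")


def setup_logging(level: int = logging.INFO) -> None:
    """Configure structured logging to stderr (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)


@dataclass
class RunConfig:
    """Parameters of the correction + filtering pipeline.

    Attributes
    ----------
    alpha:
        Significance threshold on the tail-bound p-value; candidates whose
        least-significant pairwise p-value exceeds ``alpha`` are eliminated.
    tau:
        Maximum number of candidates removed per filtering round.
    max_variants:
        If two candidates differ at more than this many multi-alignment
        columns the pair is not statistically evaluated (its p-value would be
        vanishingly small) and is treated as significant.
    max_rounds:
        Safety cap on the partition/correct iteration.
    p_convention:
        ``"specific"``: a substitution error must produce the one specific
        base the candidate carries, so Phred error probabilities are divided
        by 3 at substitution variants (indel variants undivided).
        ``"raw"``: Phred probability used as-is everywhere.
    delta_convention:
        ``"printed"``: delta = t'/mu in the Chernoff-type tail bound.
        ``"shifted"``: delta = t'/mu - 1 (bound applied exactly at t').
    p_floor, p_cap:
        Clamp for per-position error probabilities.
    n_policy:
        ``"drop"``: reads containing N are discarded with a warning.
        ``"mask"``: N bases are replaced by 'A' with quality 1 (error
        probability ~0.75, effectively a mismatch to everything).
    min_indel_length:
        Smallest gap run regarded as "large" (exon-scale) when grouping
        transcripts into gene copies.
    max_dist:
        Optional cap on edit distances in the nearest-neighbor graph
        (``None`` = unbounded).
    """

    alpha: float = 0.01
    tau: int = 10
    max_variants: int = 10
    max_rounds: int = 20
    p_convention: str = "specific"
    delta_convention: str = "printed"
    p_floor: float = 1e-7
    p_cap: float = 0.5
    n_policy: str = "drop"
    min_indel_length: int = 20
    max_dist: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.p_convention not in ("specific", "raw"):
            raise ValueError("p_convention must be 'specific' or 'raw'")
        if self.delta_convention not in ("printed", "shifted"):
            raise ValueError("delta_convention must be 'printed' or 'shifted'")
        if self.n_policy not in ("drop", "mask"):
            raise ValueError("n_policy must be 'drop' or 'mask'")
        if not 0.0 < self.p_floor <= self.p_cap < 1.0:
            raise ValueError("need 0 < p_floor <= p_cap < 1")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
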
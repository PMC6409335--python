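"""adipolinc: lincRNA discovery and functional prediction for two-group RNA-seq.

Intergenic transcript classification, multi-stage lincRNA filtering,
class characterization, NB Wald differential expression, <100 kb neighbor
and correlation-based target prediction, and QTL colocalization — plus a
seeded synthetic-study generator with planted ground truth.
"""

__version__ = "0.1.0"

from .io_formats import (
    GenomicInterval,
    QTLRecord,
    SampleInfo,
    TranscriptModel,
)
from .synthetic_data import GroundTruth, SimulationConfig, generate_study

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "SampleInfo",
    "QTLRecord",
    "SimulationConfig",
    "GroundTruth",
    "generate_study",
    "__version__",
]
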
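"""afpscan: antifreeze-protein identification from evolutionary (PSSM) features.

The pipeline encodes each protein's position-specific scoring matrix into a
400-dimensional substitution-score vector, balances the rare antifreeze
class with MWMOTE, ranks features by ensemble mRMR, selects a parsimonious
feature subset by incremental addition with an independent-test stopping
rule, trains an RBF-kernel SVM, and quantifies per-feature contributions to
the principal components of the selected features.
"""

__version__ = "0.1.0"

from .alphabet import AA_ORDER, FEATURE_NAMES, feature_index, feature_label
from .containers import (
    FeatureTable,
    ProteinSequence,
    PssmGenerationSettings,
    PssmProfile,
)

__all__ = [
    "AA_ORDER",
    "FEATURE_NAMES",
    "feature_index",
    "feature_label",
    "FeatureTable",
    "ProteinSequence",
    "PssmGenerationSettings",
    "PssmProfile",
    "__version__",
]
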
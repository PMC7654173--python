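"""Exception hierarchy.

Every failure mode a caller may want to branch on gets its own class;
pipeline stages re-raise with the stage name attached.
"""


class PolyriskError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PolyriskError, ValueError):
    """An invalid configuration value (bad frequency range, empty cohort sizes, ...)."""


class QCError(PolyriskError):
    """QC removed everything, or QC inputs are inconsistent."""


class PanelError(PolyriskError):
    """SNP panel invalid or emptied by filtering (PRS undefined)."""


class MissingSNPError(PanelError):
    """Panel SNPs absent from the genotype matrix."""

    def __init__(self, rsids):
        self.rsids = list(rsids)
        super().__init__(f"panel SNPs absent from genotype matrix: {', '.join(self.rsids)}")


class EncodingError(PolyriskError, KeyError):
    """Phenotype category without an OR in the encoding table."""


class SeparationError(PolyriskError):
    """Perfect separation in a logistic fit; the ML estimate does not exist."""

    def __init__(self, msg="perfect separation detected; consider pooling sparse "
                           "categories or removing the offending predictor"):
        super().__init__(msg)


class ConvergenceError(PolyriskError):
    """Maximum-likelihood fit failed to converge."""


class RankDeficiencyError(PolyriskError):
    """Design matrix is rank deficient."""


class AscertainmentError(PolyriskError):
    """Population does not contain enough cases or controls to subsample."""


class DegenerateInputError(PolyriskError, ValueError):
    """Input without enough variation for the requested operation
    (single-class AUC, all-equal scores for banding, ...)."""


class PipelineStageError(PolyriskError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage, original):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
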
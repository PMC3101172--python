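"""Exception hierarchy for the screen pipeline.

Every failure mode named in a module contract maps to one class here so callers
can catch at whatever granularity they need; ``MosaicError`` is the common base.
"""


class MosaicError(Exception):
    """Base class for all package errors."""


class UnknownTaxonError(MosaicError, KeyError):
    """An OTU label is not registered in the taxonomy map."""

    def __init__(self, label: str):
        super().__init__(f"OTU label not registered in taxonomy: {label!r}")
        self.label = label


class MalformedLabelError(MosaicError, ValueError):
    """An OTU label does not follow the Genus_species naming convention."""


class EmptyAlignmentError(MosaicError, ValueError):
    """Trimming removed every column of an alignment."""


class QueryTooGappyError(MosaicError, ValueError):
    """The designated query row exceeds the taxon gap-fraction threshold."""


class TooFewTaxaError(MosaicError, ValueError):
    """Fewer than four rows remain after taxon filtering."""


class NoOverlapError(MosaicError, ValueError):
    """A sequence pair shares no comparable (non-gap, non-X) columns."""

    def __init__(self, a: str, b: str):
        super().__init__(f"no comparable columns between {a!r} and {b!r}")
        self.pair = (a, b)


class InvalidCandidateSetError(MosaicError, ValueError):
    """Shared-indel candidate set is empty, unknown, or covers every row."""


class InvalidMatrixError(MosaicError, ValueError):
    """Distance matrix is non-symmetric, non-square, or contains NaN."""


class InvalidTaxaSetError(MosaicError, ValueError):
    """Bipartition query set is not a proper non-empty subset of the leaves."""


class NoEligibleTaxonError(MosaicError, ValueError):
    """No non-excluded, non-query leaf exists for a closest-taxon scan."""


class NoOutgroupError(MosaicError, ValueError):
    """No configured outgroup lineage group is represented in the tree."""


class ConfigError(MosaicError, ValueError):
    """Invalid configuration value or schema violation."""


class ScenarioError(MosaicError, ValueError):
    """A simulation scenario is missing a lineage group its label requires."""


class StageError(MosaicError, RuntimeError):
    """A pipeline stage failed; carries the stage name and offending unit."""

    def __init__(self, stage: str, unit: str, message: str):
        super().__init__(f"stage {stage!r} failed on {unit!r}: {message}")
        self.stage = stage
        self.unit = unit
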
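"""Exception types used across the package."""


class Snps2GenesError(Exception):
    """Base class for all package errors."""


class ConfigError(Snps2GenesError):
    """A configuration value is invalid or infeasible."""


class FormatError(Snps2GenesError):
    """An on-disk record failed to parse; message carries the offending location."""


class GraphError(Snps2GenesError):
    """The GO is_a edge list is not a DAG, or annotations are inconsistent."""


class SimulationError(Snps2GenesError):
    """Cohort simulation could not satisfy the case/control quotas."""


class EstimationError(Snps2GenesError):
    """A statistical estimate is undefined for the given input (e.g. monomorphic data)."""
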
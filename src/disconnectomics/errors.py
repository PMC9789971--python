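"""Exception hierarchy.

Configuration errors mean the user asked for something impossible (bad
parameters, unpackable parcellations); data-contract errors mean inputs that
exist but violate an invariant (grid mismatches, negative disconnection
counts). The CLI maps the two classes onto distinct exit codes.
"""


class DisconnectomicsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DisconnectomicsError):
    """Invalid or unsatisfiable configuration (exit code 2 in the CLI)."""


class DataContractError(DisconnectomicsError):
    """Input data violating a declared invariant (exit code 3 in the CLI)."""


class GridMismatchError(DataContractError):
    """Lesion mask and parcellation live on different voxel grids."""


class EmptyLesionError(DataContractError):
    """A requested lesion contains no voxels inside the volume."""
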
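"""Exception hierarchy for registry parsing, configuration, and pipeline stages."""


class RegistryError(Exception):
    """Base class for all registry/pipeline errors."""


class SchemaError(RegistryError):
    """A required column is missing or a file does not match its schema."""


class RowError(RegistryError):
    """A data row failed to parse (bad date, bad label); message carries the row number."""


class IntegrityError(RegistryError):
    """Cross-table referential integrity or within-table uniqueness violated."""


class ConfigError(RegistryError):
    """An invalid study or simulation configuration."""


class PipelineError(RegistryError):
    """A pipeline stage failed; message names the stage."""
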
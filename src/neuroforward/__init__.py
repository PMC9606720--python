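"""Forward modeling of LFP and MEG signals from spiking and mean-field AdEx
network models.

Submodules
----------
adex_spiking
    Point and two-compartment AdEx network simulators.
adex_meanfield
    First-order mean-field (rate) model with a fitted transfer function.
ulfp_kernel
    Unitary-LFP kernels; spike-based and rate-based LFP synthesis.
dipole_forward
    Current-dipole and volume-conductor MEG forward model.
state_metrics
    Up/down-state detection and amplitude/duration statistics.
brain_network
    Networks of coupled mean-field nodes on a (synthetic) connectome.
config / fixtures / pipeline / cli
    Configuration, fixture generators, the end-to-end validation pipeline
    and the command-line interface.
"""

from importlib import resources as _resources

__version__ = "0.1.0"


def data_path(name: str):
    """Path to a shipped parameter file in ``neuroforward/data``."""
    return _resources.files("neuroforward").joinpath("data", name)


from . import (  # noqa: E402
    adex_meanfield,
    adex_spiking,
    brain_network,
    dipole_forward,
    state_metrics,
    ulfp_kernel,
)

__all__ = [
    "adex_spiking",
    "adex_meanfield",
    "ulfp_kernel",
    "dipole_forward",
    "state_metrics",
    "brain_network",
    "data_path",
    "__version__",
]
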
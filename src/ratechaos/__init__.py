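"""ratechaos: rate chaos in balanced spiking networks.

Simulators (rate and integrate-and-fire), dynamical mean-field theory
solvers, chaos metrics and sparse stability spectra for randomly connected
inhibitory and excitatory-inhibitory networks in the balanced regime.
"""

from . import transfer  # noqa: F401

__version__ = "0.1.0"


def __getattr__(name):
    # heavier submodules (numba compilation, scipy.sparse) load lazily
    if name in ("network", "spiking", "metrics", "spectra", "dmft",
                "targets", "experiments"):
        import importlib
        return importlib.import_module(f".{name}", __name__)
    raise AttributeError(name)
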
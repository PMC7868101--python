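"""Built-in oracle checks, shared by the CLI ``selftest`` subcommand.

Fast verifications of the numerical core: exact adjointness of the
encoding operator (dot-product test, direct-DFT backend), agreement of
the gridding NUFFT backend with the direct transform, and the STCR
analytic gradient against central finite differences.
"""

from __future__ import annotations

from .evaluation import gradient_accuracy, operator_accuracy


def run_selftest(seed: int = 0) -> dict[str, bool]:
    ops = operator_accuracy(seed)
    grad = gradient_accuracy(seed)
    return {
        "adjoint dot-product (dft) <= 1e-10": ops["adjoint_relative_error"] <= 1e-10,
        "nufft vs direct dft <= 1e-5": ops["nufft_vs_dft_relative_error"] <= 1e-5,
        "stcr gradient vs finite differences <= 1e-6": grad["gradient_relative_error"]
        <= 1e-6,
    }
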
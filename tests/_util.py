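import numpy as np

import solvtol as st


def exp_series(mu, od0=0.05, t_end=6.0, n=7, species="sp", solvent="S", conc=0.0, rep="r1"):
    """Exact exponential OD course, no lag, no plateau."""
    t = np.linspace(0.0, t_end, n)
    return st.ODSeries(species, solvent, conc, rep, t, od0 * np.exp(mu * t))
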
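"""Independent oracles used by the test suite.

The brute-force likelihood enumerates every alignment scenario (sequences
of match columns, deletion blocks and insertion blocks) explicitly and
sums their probabilities; it shares no code with the dynamic-programming
implementation it checks.
"""

from shmindel.core import IndelModel, gamma_del, gamma_ins, match_prob


def brute_force_likelihood(s: str, t: str, mu: float, model: IndelModel) -> float:
    """Explicit sum over all alignment scenarios (exponential; keep L <= ~8)."""
    theta = model.theta_max

    def rec(i: int, j: int) -> float:
        if i == len(s) and j == len(t):
            return 1.0
        total = 0.0
        if i < len(s) and j < len(t):
            total += match_prob(s[i], t[j], mu, model) * rec(i + 1, j + 1)
        for ell in range(1, min(theta, len(t) - j) + 1):
            total += gamma_del(ell, mu, model) * rec(i, j + ell)
        for ell in range(1, min(theta, len(s) - i) + 1):
            total += gamma_ins(ell, mu, model) * rec(i + ell, j)
        return total

    return rec(0, 0)
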
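"""Independent brute-force oracles used only by the tests."""


def dp_levenshtein(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance, case-insensitive."""
    a, b = a.casefold(), b.casefold()
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]
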
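"""Independent brute-force oracles used across the test suite.

Each function recomputes a statistic from first principles, by enumeration
or the defining recursion, sharing no code with the implementation it
checks.
"""

from functools import lru_cache


def levenshtein_recursive(a: str, b: str) -> int:
    """Edit distance straight from the defining recursion (memoized)."""

    @lru_cache(maxsize=None)
    def d(i, j):
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            d(i - 1, j) + 1,
            d(i, j - 1) + 1,
            d(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )

    return d(len(a), len(b))


def clonality_by_enumeration(assignment):
    """All clonality statistics of a cell -> clonotype-id assignment list.

    Everything is computed with plain loops over the assignment: frequencies
    by counting, ranks by full sort, classes by definition, top-n share and
    the upper-quintile count by cumulative enumeration.
    """
    freq = {}
    for c in assignment:
        freq[c] = freq.get(c, 0) + 1
    n_cells = len(assignment)
    ordered = sorted(freq, key=lambda c: (-freq[c], c))
    rank = {c: i + 1 for i, c in enumerate(ordered)}

    classes = {}
    for c in ordered:
        if freq[c] == 1:
            classes[c] = "singleton"
        elif freq[c] == 2:
            classes[c] = "doubleton"
        elif rank[c] <= 10:
            classes[c] = "top10"
        else:
            classes[c] = "other"

    def top_share(n):
        cells = sum(freq[c] for c in ordered[:n])
        return 100.0 * cells / n_cells

    cum = 0
    quintile_count = len(ordered)
    for i, c in enumerate(ordered, start=1):
        cum += freq[c]
        if cum >= 0.2 * n_cells:
            quintile_count = i
            break

    partition = {}
    for c in ordered:
        if classes[c] == "top10":
            partition[f"clonotype_{rank[c]}"] = 100.0 * freq[c] / n_cells
    partition["other"] = (
        100.0 * sum(freq[c] for c in ordered if classes[c] == "other") / n_cells
    )
    partition["doubletons"] = (
        100.0 * sum(freq[c] for c in ordered if classes[c] == "doubleton") / n_cells
    )
    partition["singletons"] = (
        100.0 * sum(freq[c] for c in ordered if classes[c] == "singleton") / n_cells
    )
    return {
        "freq": freq,
        "rank": rank,
        "classes": classes,
        "top_share": top_share,
        "upper_quintile": quintile_count,
        "partition": partition,
        "n_singletons": sum(1 for c in ordered if classes[c] == "singleton"),
        "n_doubletons": sum(1 for c in ordered if classes[c] == "doubleton"),
    }


def silhouette_by_loops(points, labels):
    """Mean euclidean silhouette width computed with explicit loops."""
    import math

    n = len(points)

    def dist(p, q):
        return math.sqrt(sum((pi - qi) ** 2 for pi, qi in zip(p, q)))

    widths = []
    for i in range(n):
        same = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not same:
            widths.append(0.0)
            continue
        a = sum(dist(points[i], points[j]) for j in same) / len(same)
        b = math.inf
        for other in set(labels) - {labels[i]}:
            members = [j for j in range(n) if labels[j] == other]
            b = min(b, sum(dist(points[i], points[j]) for j in members) / len(members))
        widths.append((b - a) / max(a, b))
    return sum(widths) / n


def bh_adjust_stepup(pvalues):
    """Benjamini-Hochberg step-up adjustment, written out longhand."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        value = min(pvalues[i] * m / (pos + 1), running_min)
        running_min = value
        adjusted[i] = value
    return adjusted


def gene_stats_by_loops(matrix):
    """base_mean / Fano dispersion / coverage per row via explicit loops."""
    rows = []
    for row in matrix:
        n = len(row)
        mean = sum(row) / n
        var = sum((x - mean) ** 2 for x in row) / n
        dispersion = var / mean if mean > 0 else 0.0
        coverage = sum(1 for x in row if x > 0)
        rows.append((mean, dispersion, coverage))
    return rows
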
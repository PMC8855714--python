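"""Exhaustively test resolution across every topology on n leaves.

Enumerates all rooted labeled topologies (polytomies included), labels
every node with the descendant/sibling scheme (e.g. NAB_CD), derives
where the two test definitions — minimum clade of {A,B} and maximum
clade including A but excluding C — must resolve, resolves them, and
reports the pass rate.  A 100% pass rate means resolution is correct on
every possible branching structure, not just a curated example.
"""

from phyx import run_sweep

for n in range(2, 7):
    report = run_sweep(n)
    counts = report.counts
    print(
        f"n={n}: {counts['total']:5d} topologies "
        f"({counts['bifurcating']:4d} bifurcating, {counts['multifurcating']:5d} multifurcating) "
        f"-> {report.passed}/{report.checked} checks passed "
        f"({report.pass_fraction:.0%})"
    )

example = run_sweep(4).records[0]
print(f"\nexample record: {example.newick}")
print(f"  min clade {{A,B}}: expected {example.expected_min}, resolved {example.resolved_min}")
print(f"  max clade A\\C:    expected {example.expected_max}, resolved {example.resolved_max}")
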
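"""A scripted run of the interactive reference-point session.

The decision-maker first sees the attainable range of each criterion, then
states aspiration points; each is projected onto the Pareto frontier and the
achieved values are displayed.  Here the "user input" is pre-scripted so the
example runs unattended; replace ``istream`` with ``sys.stdin`` (or run
``refpoint interactive <config>``) for a live session.
"""

import io

from refpoint import from_point_list, run_interactive_session

problem = from_point_list([(0, 3), (2, 2), (3, 0)])

scripted_input = io.StringIO(
    "3 3\n"   # utopian aspiration: both criteria at their ideal
    "0 3\n"   # prioritize the second criterion completely
    "q\n"
)
state = run_interactive_session(
    problem,
    istream=scripted_input,
    criteria_names=["habitat", "harvest"],
)
print(f"\nsession history: {len(state.history)} iteration(s)")
for z_bar, sol in state.history:
    print(f"  aspired {tuple(map(float, z_bar))} -> achieved {tuple(map(float, sol.criteria))}")
print(
    "-> the utopian aspiration lands on the balanced efficient point (2, 2); "
    "an extreme aspiration is returned unchanged because it is already "
    "non-dominated."
)
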
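"""Compiled inner loops of the automaton.

Everything here operates on flat row-major arrays (``index = y * M + x``)
plus a precomputed neighbor table of shape ``(M*M, 4)`` whose columns follow
the fixed N, E, S, W direction order; ``-1`` marks a missing neighbor, which
counts as OUTSIDE for the state constraints but can never be entered.

Randomness is a self-contained xorshift128+ stream held in a ``uint64[2]``
state array.  Every stochastic choice draws from it in a documented fixed
order over row-major / table-order candidate lists, so runs are reproducible
bit-for-bit per seed across platforms.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# walk policies
WALK_STABLE = 0     # wander, but rest only at locally safe (simple) sites
WALK_FREE = 1       # wander and rest anywhere (cytoplasm preferred)
WALK_CYTO_ONLY = 2  # stop as soon as no cytoplasm neighbor exists

PHASE_FORAGING = 0
PHASE_SHRINKING = 1

TERM_RUNNING = 0
TERM_NO_CHANGE = 1
TERM_CAP = 2

# int64 counter slots shared between the driver and the chunk kernel
I_ITER = 0
I_PHASE = 1
I_PD = 2
I_CE = 3
I_NCOMP = 4
I_AREA = 5
I_QUIET = 6
I_SWITCH = 7
I_TERM = 8
I_DIRTY = 9
I_VIOL = 10
I_FORAGE_AREA_CHANGES = 11
I_SHRINK_ACTIONS = 12
I_SHRINK_DECREMENTS = 13
I_SHRINK_REJECTED = 14  # eroding events whose bubble retreated and undid itself
I_NOOPS = 15
I_STAMP = 16
I_DRAIN_OK = 17
N_ICOUNTERS = 18

F_TRUE_ITERS = 0
F_P_RANDOM = 1
N_FCOUNTERS = 2


# ---------------------------------------------------------------------------
# RNG: xorshift128+, seeded through splitmix64
# ---------------------------------------------------------------------------

@njit(cache=True)
def _splitmix64(z):
    z = (z + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True)
def seed_rng(seed, state):
    z = np.uint64(seed)
    state[0] = _splitmix64(z)
    state[1] = _splitmix64(state[0])
    if state[0] == 0 and state[1] == 0:
        state[0] = np.uint64(0xDEADBEEF)


@njit(cache=True, inline="always")
def next_u64(state):
    x = state[0]
    y = state[1]
    state[0] = y
    x ^= x << np.uint64(23)
    x ^= x >> np.uint64(17)
    x ^= y ^ (y >> np.uint64(26))
    state[1] = x
    return (x + y) & np.uint64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True, inline="always")
def rand_below(state, n):
    """Uniform integer in [0, n). Modulo reduction of a 64-bit draw; the bias
    is < n / 2**64 and irrelevant for the candidate-list sizes used here."""
    return np.int64(next_u64(state) % np.uint64(n))


@njit(cache=True, inline="always")
def rand_unit(state):
    return (next_u64(state) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


# ---------------------------------------------------------------------------
# state constraints
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _outside_count(states, nbr, i):
    c = 0
    for d in range(4):
        j = nbr[i, d]
        if j < 0 or states[j] == 0:
            c += 1
    return c


@njit(cache=True)
def repair_all(states, nbr):
    """Single deterministic pass restoring the two state constraints:
    an organism site becomes MEMBRANE iff it has at least one OUTSIDE
    neighbor (off-grid counts as OUTSIDE), else CYTOPLASM.  Idempotent."""
    n = states.shape[0]
    for i in range(n):
        if states[i] != 0:
            states[i] = 2 if _outside_count(states, nbr, i) > 0 else 1


@njit(cache=True)
def repair_touched(states, nbr, touched, cnt):
    """Re-derive the state label of every touched site and its neighbors.

    Membrane/cytoplasm labels depend only on the OUTSIDE-ness of the
    4-neighborhood, which repair never changes, so recomputing an arbitrary
    superset of the modified sites in any order is exact."""
    for k in range(cnt):
        i = touched[k]
        if states[i] != 0:
            states[i] = 2 if _outside_count(states, nbr, i) > 0 else 1
        for d in range(4):
            j = nbr[i, d]
            if j >= 0 and states[j] != 0:
                states[j] = 2 if _outside_count(states, nbr, j) > 0 else 1


@njit(cache=True)
def count_violations(states, nbr):
    """Number of sites violating the membrane/cytoplasm constraints."""
    n = states.shape[0]
    v = 0
    for i in range(n):
        if states[i] == 1 and _outside_count(states, nbr, i) > 0:
            v += 1
        elif states[i] == 2 and _outside_count(states, nbr, i) == 0:
            v += 1
    return v


@njit(cache=True, inline="always")
def is_eligible(states, obstacle, nbr, i, s_max):
    """Stimulus eligibility: a MEMBRANE site with 1..s_max OUTSIDE neighbors
    (off-grid and obstacles count -- the cap excludes nearly detached
    protrusion tips) and at least one *enterable* OUTSIDE neighbor (in-grid,
    non-obstacle) so conserving introduction cannot fail."""
    if states[i] != 2:
        return False
    oc = 0
    enterable = False
    for d in range(4):
        j = nbr[i, d]
        if j < 0:
            oc += 1
        elif states[j] == 0:
            oc += 1
            if obstacle[j] == 0:
                enterable = True
    return (1 <= oc <= s_max) and enterable


@njit(cache=True)
def collect_eligible(states, obstacle, nbr, s_max, out):
    """All eligible stimuli in row-major order. Returns the count."""
    n = states.shape[0]
    c = 0
    for i in range(n):
        if is_eligible(states, obstacle, nbr, i, s_max):
            out[c] = i
            c += 1
    return c


@njit(cache=True)
def collect_eligible_subset(states, obstacle, nbr, s_max, subset, out):
    c = 0
    for k in range(subset.shape[0]):
        i = subset[k]
        if is_eligible(states, obstacle, nbr, i, s_max):
            out[c] = i
            c += 1
    return c


@njit(cache=True)
def mark_cyto_components(states, labels, comp_cyto, ncomp):
    """Flag components that still contain CYTOPLASM.  A bubble can only
    percolate where interior fluid remains, so stimulation is pointless --
    and the dynamics provably frozen -- on all-membrane components."""
    for l in range(ncomp + 1):
        comp_cyto[l] = 0
    for i in range(states.shape[0]):
        if states[i] == 1:
            comp_cyto[labels[i]] = 1


@njit(cache=True)
def collect_eligible_gated(states, obstacle, nbr, s_max, labels, comp_cyto, out):
    """Eligible stimuli whose component still holds cytoplasm (row-major)."""
    n = states.shape[0]
    c = 0
    for i in range(n):
        if comp_cyto[labels[i]] == 1 and is_eligible(states, obstacle, nbr, i, s_max):
            out[c] = i
            c += 1
    return c


@njit(cache=True)
def collect_eligible_gated_subset(states, obstacle, nbr, s_max, labels, comp_cyto,
                                  subset, out):
    c = 0
    for k in range(subset.shape[0]):
        i = subset[k]
        if comp_cyto[labels[i]] == 1 and is_eligible(states, obstacle, nbr, i, s_max):
            out[c] = i
            c += 1
    return c


@njit(cache=True)
def drain_possible(states, nbr, zone_sites, protected, visited, queue):
    """Can any shrinking event still remove material?

    A shrinking bubble removes exactly one site: the safe, non-terminal
    resting place it finds while percolating from a zone stimulus.  If no
    such site is reachable through organism material from any zone, every
    event retreats and undoes itself, so the run is frozen.  This is also
    the natural convergence point: in a finished network every leaf is a
    terminal pad and nothing else can be retracted."""
    n = states.shape[0]
    for i in range(n):
        visited[i] = 0
    head = 0
    tail = 0
    for k in range(zone_sites.shape[0]):
        i = zone_sites[k]
        if states[i] > 0 and visited[i] == 0:
            visited[i] = 1
            queue[tail] = i
            tail += 1
    while head < tail:
        u = queue[head]
        head += 1
        if protected[u] == 0 and safe_rest(states, nbr, u):
            return 1
        for d in range(4):
            j = nbr[u, d]
            if j >= 0 and states[j] > 0 and visited[j] == 0:
                visited[j] = 1
                queue[tail] = j
                tail += 1
    return 0


@njit(cache=True)
def collect_state_in_subset(states, subset, want, out):
    c = 0
    for k in range(subset.shape[0]):
        i = subset[k]
        if states[i] == want:
            out[c] = i
            c += 1
    return c


# ---------------------------------------------------------------------------
# resting-site safety (stochastic skeletonization)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def safe_rest(states, nbr, p):
    """May a bubble come to rest at (now OUTSIDE) site ``p``?

    Safe means the organism material around ``p`` remains locally one piece
    without it: the occupied arcs of the 8-ring that contain at least one
    cardinal neighbor must number at most one (a simple-point / crossing
    number test; diagonals are reached by composing two cardinal steps, in
    either order so identified edges work).  Interior positions (no OUTSIDE
    cardinal) are unsafe -- bubbles must surface rather than leave voids --
    and so are positions whose removal would locally split the material,
    which protects thin paths from being severed.  Tips, flat surfaces and
    width-2 material are safe, so surfaces retract and dead ends prune while
    the skeleton survives."""
    # cardinal occupancy (ring positions 0,2,4,6 = N,E,S,W)
    oN = False
    oE = False
    oS = False
    oW = False
    out4 = 0
    j = nbr[p, 0]
    if j >= 0 and states[j] > 0:
        oN = True
    else:
        out4 += 1
    j = nbr[p, 1]
    if j >= 0 and states[j] > 0:
        oE = True
    else:
        out4 += 1
    j = nbr[p, 2]
    if j >= 0 and states[j] > 0:
        oS = True
    else:
        out4 += 1
    j = nbr[p, 3]
    if j >= 0 and states[j] > 0:
        oW = True
    else:
        out4 += 1
    if out4 == 0:
        return False  # interior void
    if out4 == 4:
        return True  # isolated bubble, nothing to disconnect
    # diagonals NE(1), SE(3), SW(5), NW(7) via two-step composition
    occ0 = 1 if oN else 0
    occ2 = 1 if oE else 0
    occ4 = 1 if oS else 0
    occ6 = 1 if oW else 0
    occ1 = 0
    occ3 = 0
    occ5 = 0
    occ7 = 0
    for k in range(4):
        d1 = k
        d2 = (k + 1) % 4
        j = nbr[p, d1]
        q = nbr[j, d2] if j >= 0 else -1
        if q < 0:
            j2 = nbr[p, d2]
            q = nbr[j2, d1] if j2 >= 0 else -1
        o = 1 if (q >= 0 and states[q] > 0) else 0
        if k == 0:
            occ1 = o
        elif k == 1:
            occ3 = o
        elif k == 2:
            occ5 = o
        else:
            occ7 = o
    # count occupied arcs of the 8-cycle that contain a cardinal
    # anchor at an empty cardinal (one exists: out4 >= 1)
    start = 0
    if not oN:
        start = 0
    elif not oE:
        start = 2
    elif not oS:
        start = 4
    else:
        start = 6
    arcs = 0
    in_arc = False
    has_card = False
    for t in range(1, 9):
        k = (start + t) % 8
        if k == 0:
            o = occ0
        elif k == 1:
            o = occ1
        elif k == 2:
            o = occ2
        elif k == 3:
            o = occ3
        elif k == 4:
            o = occ4
        elif k == 5:
            o = occ5
        elif k == 6:
            o = occ6
        else:
            o = occ7
        if o == 1:
            in_arc = True
            if k % 2 == 0:
                has_card = True
        else:
            if in_arc and has_card:
                arcs += 1
            in_arc = False
            has_card = False
    if in_arc and has_card:
        arcs += 1
    return arcs <= 1


@njit(cache=True)
def refresh_pocket_mask(states, nbr, M, bounded, special, labels0, queue, visited):
    """Mark organism sites bordering an enclosed OUTSIDE pocket in ``special``.

    A pocket is OUTSIDE region unreachable from the border (bounded) or any
    OUTSIDE component other than the largest (closed surfaces).  Bubbles may
    additionally rest on pocket-bordering material: cutting a closed ring at
    one point merges the pocket with the outside without disconnecting the
    ring, which is how redundant loops are dissolved."""
    n = states.shape[0]
    for i in range(n):
        special[i] = 0
        visited[i] = 0
    if bounded:
        head = 0
        tail = 0
        for x in range(M):
            for edge in range(2):
                i = x if edge == 0 else (M - 1) * M + x
                if states[i] == 0 and visited[i] == 0:
                    visited[i] = 1
                    queue[tail] = i
                    tail += 1
        for y in range(M):
            for edge in range(2):
                i = y * M if edge == 0 else y * M + M - 1
                if states[i] == 0 and visited[i] == 0:
                    visited[i] = 1
                    queue[tail] = i
                    tail += 1
        while head < tail:
            u = queue[head]
            head += 1
            for d in range(4):
                j = nbr[u, d]
                if j >= 0 and states[j] == 0 and visited[j] == 0:
                    visited[j] = 1
                    queue[tail] = j
                    tail += 1
        found = 0
        for i in range(n):
            if states[i] == 0 and visited[i] == 0:
                for d in range(4):
                    j = nbr[i, d]
                    if j >= 0 and states[j] > 0:
                        special[j] = 1
                        found += 1
        return found
    nc0 = label_region(states, nbr, 0, labels0, queue)
    if nc0 <= 1:
        return 0
    sizes = np.zeros(nc0 + 1, dtype=np.int64)
    for i in range(n):
        if states[i] == 0:
            sizes[labels0[i]] += 1
    main = 1
    for l in range(2, nc0 + 1):
        if sizes[l] > sizes[main]:
            main = l
    found = 0
    for i in range(n):
        if states[i] == 0 and labels0[i] != main:
            for d in range(4):
                j = nbr[i, d]
                if j >= 0 and states[j] > 0:
                    special[j] = 1
                    found += 1
    return found


# ---------------------------------------------------------------------------
# bubble events
# ---------------------------------------------------------------------------

@njit(cache=True)
def introduce(states, origin, obstacle, nbr, t, conserving, rng, touched):
    """Introduce a bubble at stimulus ``t``.  Conserving mode first displaces
    the stimulus material into a uniformly chosen enterable OUTSIDE neighbor
    (area unchanged); eroding mode simply deletes it (area -1).  Returns the
    number of touched sites written (0 if ``t`` had no enterable neighbor in
    conserving mode, which eligibility rules out)."""
    cnt = 0
    if conserving:
        # displaced material settles where it is best supported: among the
        # enterable OUTSIDE neighbors, prefer those touching the most
        # organism material (crevices fill before protrusions sprout),
        # which keeps crawling cells compact
        k = 0
        best = -1
        choice = np.empty(4, dtype=np.int64)
        for d in range(4):
            j = nbr[t, d]
            if j >= 0 and states[j] == 0 and obstacle[j] == 0:
                sup = 0
                for d2 in range(4):
                    q = nbr[j, d2]
                    if q >= 0 and states[q] > 0:
                        sup += 1
                if sup > best:
                    best = sup
                    choice[0] = j
                    k = 1
                elif sup == best:
                    choice[k] = j
                    k += 1
        if k == 0:
            return 0
        b = choice[rand_below(rng, k)]
        states[b] = states[t]
        origin[b] = origin[t]
        touched[cnt] = b
        cnt += 1
    states[t] = 0
    origin[t] = 0
    touched[cnt] = t
    cnt += 1
    return cnt


@njit(cache=True)
def walk(states, origin, nbr, start, n_swaps, membrane_budget, policy, leak,
         rng, touched, tcnt, forbid, protected):
    """Percolate the bubble from ``start`` by swapping with organism material.

    The bubble travels through the interior: each swap picks a uniform
    CYTOPLASM neighbor, falling back to MEMBRANE only when no cytoplasm is
    adjacent (at most ``membrane_budget`` membrane swaps per walk -- the
    cytoskeleton resists transport, which bounds travel along thin
    all-membrane structures).  Under the ``stable`` policy the bubble is
    then *expelled through the membrane* wherever its percolation ended:
    it keeps swapping across membrane until it reaches a position where
    resting is safe (see :func:`safe_rest`; sites flagged in ``special`` --
    pocket borders -- also count), and if expulsion fails it retreats along
    its trail to the last safe position, undoing swaps as it goes, so
    material is never severed.  ``free`` rests wherever the percolation
    stops; ``cyto_only`` swaps only with cytoplasm and rests where it stops.

    ``forbid`` (the introduction site) is never a swap target: the bubble
    does not exit where it entered.  Sites flagged in ``protected`` (the
    terminal pads) are never resting places: a bubble may pass through a
    zone but cannot delete its material, which keeps distant walks from
    pruning away another terminal's anchor.  Swaps move material (state label and
    origin id) onto the bubble's site and move the bubble onward; area is
    conserved.  Appends touched sites in pairs into ``touched`` starting at
    ``tcnt``; returns the new count and the resting position."""
    pos = start
    walk_base = tcnt
    mem_used = 0
    choice = np.empty(4, dtype=np.int64)
    mchoice = np.empty(4, dtype=np.int64)
    for _ in range(n_swaps):
        k = 0
        km = 0
        for d in range(4):
            j = nbr[pos, d]
            if j < 0 or j == forbid:
                continue
            if states[j] == 1:
                choice[k] = j
                k += 1
            elif states[j] == 2 and policy != WALK_CYTO_ONLY and mem_used < membrane_budget:
                mchoice[km] = j
                km += 1
        if k == 0 and km == 0:
            break
        use_mem = False
        if k == 0:
            use_mem = True
        elif km > 0 and leak > 0.0:
            # occasional crossing into the cytoskeleton even when interior
            # routes exist, so bubbles can pass between cytoplasm pockets
            if rand_unit(rng) < leak:
                use_mem = True
        if use_mem:
            c = mchoice[rand_below(rng, km)]
            mem_used += 1
        else:
            c = choice[rand_below(rng, k)]
        states[pos] = states[c]
        origin[pos] = origin[c]
        states[c] = 0
        origin[c] = 0
        touched[tcnt] = pos
        tcnt += 1
        touched[tcnt] = c
        tcnt += 1
        pos = c
    if policy == WALK_STABLE:
        # expulsion: keep the bubble moving -- through cytoplasm or across
        # membrane -- until it surfaces at a safe resting place
        for _ in range(n_swaps):
            if protected[pos] == 0 and safe_rest(states, nbr, pos):
                return tcnt, pos
            k = 0
            for d in range(4):
                j = nbr[pos, d]
                if j < 0 or j == forbid:
                    continue
                s = states[j]
                if s == 1 or (s == 2 and mem_used < membrane_budget):
                    choice[k] = j
                    k += 1
            if k == 0:
                break
            c = choice[rand_below(rng, k)]
            if states[c] == 2:
                mem_used += 1
            states[pos] = states[c]
            origin[pos] = origin[c]
            states[c] = 0
            origin[c] = 0
            touched[tcnt] = pos
            tcnt += 1
            touched[tcnt] = c
            tcnt += 1
            pos = c
        if protected[pos] == 0 and safe_rest(states, nbr, pos):
            return tcnt, pos
        # no way out: retreat along the trail to the last safe position
        while tcnt > walk_base:
            if protected[pos] == 0 and safe_rest(states, nbr, pos):
                return tcnt, pos
            c = touched[tcnt - 1]
            a = touched[tcnt - 2]
            states[c] = states[a]
            origin[c] = origin[a]
            states[a] = 0
            origin[a] = 0
            pos = a
            tcnt -= 2
    return tcnt, pos


@njit(cache=True)
def bubble_event(states, origin, obstacle, nbr, t, conserving, n_swaps,
                 membrane_budget, policy, leak, rng, touched, protected):
    """One full stimulus event: introduce, percolate, local repair.
    Returns the area delta (0 or -1).

    Under the ``stable`` policy an event whose walk finds no safe resting
    place anywhere retreats all the way and undoes itself -- conserving mode
    takes back its displacement, eroding mode restores the deleted stimulus
    -- leaving the lattice unchanged: a bubble that cannot pass through the
    organism is rejected at the membrane.  Returns 0 for such rejected
    events."""
    st0 = states[t]
    or0 = origin[t]
    cnt = introduce(states, origin, obstacle, nbr, t, conserving, rng, touched)
    if cnt == 0:
        return 0
    cnt, pos = walk(states, origin, nbr, t, n_swaps, membrane_budget, policy,
                    leak, rng, touched, cnt, t, protected)
    if policy == WALK_STABLE and pos == t:
        # full retreat: the introduction itself is undone
        if conserving:
            if not safe_rest(states, nbr, t):
                b = touched[0]
                states[t] = states[b]
                origin[t] = origin[b]
                states[b] = 0
                origin[b] = 0
            repair_touched(states, nbr, touched, cnt)
            return 0
        states[t] = st0
        origin[t] = or0
        repair_touched(states, nbr, touched, cnt)
        return 0
    repair_touched(states, nbr, touched, cnt)
    return 0 if conserving else -1


# ---------------------------------------------------------------------------
# components, zone metrics, loop (pocket) detection
# ---------------------------------------------------------------------------

@njit(cache=True)
def label_components(states, nbr, labels, queue):
    """4-connected components of organism sites (states > 0) under the
    topology's neighbor relation.  Writes labels 1..k (0 elsewhere) and
    returns k."""
    n = states.shape[0]
    for i in range(n):
        labels[i] = 0
    nc = 0
    for i in range(n):
        if states[i] > 0 and labels[i] == 0:
            nc += 1
            labels[i] = nc
            head = 0
            tail = 0
            queue[tail] = i
            tail += 1
            while head < tail:
                u = queue[head]
                head += 1
                for d in range(4):
                    j = nbr[u, d]
                    if j >= 0 and states[j] > 0 and labels[j] == 0:
                        labels[j] = nc
                        queue[tail] = j
                        tail += 1
    return nc


@njit(cache=True)
def label_region(mask_states, nbr, want, labels, queue):
    """Components of sites whose state equals ``want`` (used for the OUTSIDE
    region in pocket detection)."""
    n = mask_states.shape[0]
    for i in range(n):
        labels[i] = 0
    nc = 0
    for i in range(n):
        if mask_states[i] == want and labels[i] == 0:
            nc += 1
            labels[i] = nc
            head = 0
            tail = 0
            queue[tail] = i
            tail += 1
            while head < tail:
                u = queue[head]
                head += 1
                for d in range(4):
                    j = nbr[u, d]
                    if j >= 0 and mask_states[j] == want and labels[j] == 0:
                        labels[j] = nc
                        queue[tail] = j
                        tail += 1
    return nc


@njit(cache=True)
def zone_metrics(states, labels, zone_sites, zone_of, n_zones, lbl_stamp, stamp):
    """points_discovered (zones with >= 1 organism site) and cells_effective
    (distinct components holding >= 1 zone site).  ``zone_sites`` is grouped
    by zone via the parallel ``zone_of`` array; ``lbl_stamp`` is an M*M+1
    scratch array stamped with ``stamp`` to deduplicate labels in O(1)."""
    pd = 0
    ce = 0
    cur_zone = -1
    found = False
    for k in range(zone_sites.shape[0]):
        z = zone_of[k]
        if z != cur_zone:
            cur_zone = z
            found = False
        i = zone_sites[k]
        if states[i] > 0:
            if not found:
                pd += 1
                found = True
            l = labels[i]
            if lbl_stamp[l] != stamp:
                lbl_stamp[l] = stamp
                ce += 1
    return pd, ce


@njit(cache=True)
def zones_in_one_component(states, labels, zone_sites, zone_of, n_zones):
    """True iff some single component contains at least one site of every
    zone."""
    if n_zones == 0:
        return True
    max_checks = zone_sites.shape[0]
    lab = np.empty(max_checks, dtype=np.int64)
    nzones_of = np.empty(max_checks, dtype=np.int64)
    last_zone = np.empty(max_checks, dtype=np.int64)
    nl = 0
    for k in range(zone_sites.shape[0]):
        i = zone_sites[k]
        if states[i] == 0:
            continue
        l = labels[i]
        z = zone_of[k]
        idx = -1
        for m in range(nl):
            if lab[m] == l:
                idx = m
                break
        if idx < 0:
            lab[nl] = l
            nzones_of[nl] = 1
            last_zone[nl] = z
            nl += 1
        elif last_zone[idx] != z:
            nzones_of[idx] += 1
            last_zone[idx] = z
    for m in range(nl):
        if nzones_of[m] == n_zones:
            return True
    return False


@njit(cache=True)
def pocket_loops(states, nbr, M, bounded, zone_sites, labels, labels0, queue, visited):
    """Flood-fill loop check: does a solution component (one holding a zone
    site) enclose an OUTSIDE pocket unreachable from the main outside region?

    On the bounded square the main region is everything reachable from
    OUTSIDE border sites; on closed surfaces it is the largest OUTSIDE
    component.  Returns 1 if a pocket borders a solution component."""
    n = states.shape[0]
    ncomp = label_components(states, nbr, labels, queue)
    sol = np.zeros(ncomp + 1, dtype=np.uint8)
    for k in range(zone_sites.shape[0]):
        i = zone_sites[k]
        if states[i] > 0:
            sol[labels[i]] = 1
    for i in range(n):
        visited[i] = 0
    if bounded:
        head = 0
        tail = 0
        for x in range(M):
            for edge in range(2):
                i = x if edge == 0 else (M - 1) * M + x
                if states[i] == 0 and visited[i] == 0:
                    visited[i] = 1
                    queue[tail] = i
                    tail += 1
        for y in range(M):
            for edge in range(2):
                i = y * M if edge == 0 else y * M + M - 1
                if states[i] == 0 and visited[i] == 0:
                    visited[i] = 1
                    queue[tail] = i
                    tail += 1
        while head < tail:
            u = queue[head]
            head += 1
            for d in range(4):
                j = nbr[u, d]
                if j >= 0 and states[j] == 0 and visited[j] == 0:
                    visited[j] = 1
                    queue[tail] = j
                    tail += 1
        for i in range(n):
            if states[i] == 0 and visited[i] == 0:
                for d in range(4):
                    j = nbr[i, d]
                    if j >= 0 and states[j] > 0 and sol[labels[j]] == 1:
                        return 1
        return 0
    nc0 = label_region(states, nbr, 0, labels0, queue)
    if nc0 <= 1:
        return 0
    sizes = np.zeros(nc0 + 1, dtype=np.int64)
    for i in range(n):
        if states[i] == 0:
            sizes[labels0[i]] += 1
    main = 1
    for l in range(2, nc0 + 1):
        if sizes[l] > sizes[main]:
            main = l
    for i in range(n):
        if states[i] == 0 and labels0[i] != main:
            for d in range(4):
                j = nbr[i, d]
                if j >= 0 and states[j] > 0 and sol[labels[j]] == 1:
                    return 1
    return 0


# ---------------------------------------------------------------------------
# the driver chunk
# ---------------------------------------------------------------------------

@njit(cache=True)
def run_chunk(states, origin, obstacle, nbr,
              zone_sites, zone_of, n_zones, cells_initial,
              n_swaps, membrane_budget, s_max, cap, threshold,
              enforce_tree, policy, leak,
              check_constraints, allow_fastforward, bounded, M,
              rng, ic, fc,
              labels, labels0, queue, cand, touched, lbl_stamp, visited, special,
              comp_cyto, protected, trace, trace_every, max_iters):
    """Advance the two-phase run by up to ``max_iters`` iterations.

    Per iteration the random draws occur in this fixed order: foraging --
    (1) the uniform deciding global vs discovered-zone stimulus, (2) the
    stimulus index into the row-major candidate list, (3) the entry-neighbor
    index, (4) one draw per walk swap; shrinking -- (1) the zone index,
    (2) the stimulus (or direct-removal) index within it, then (3)-(4) as
    above.  Once every zone is simultaneously without stimuli and without
    interior cytoplasm nothing can ever change again; the run is then
    fast-forwarded to its termination point.

    Returns the number of trace rows written.  Termination state is left in
    ``ic[I_TERM]``.
    """
    n_trace = 0
    it_done = 0
    while it_done < max_iters and ic[I_TERM] == TERM_RUNNING:
        it = ic[I_ITER]
        if it >= cap:
            ic[I_TERM] = TERM_CAP
            break

        if ic[I_PHASE] == PHASE_FORAGING:
            ncomp = label_components(states, nbr, labels, queue)
            mark_cyto_components(states, labels, comp_cyto, ncomp)
            ic[I_NCOMP] = ncomp
            ic[I_DIRTY] = 0
            ic[I_STAMP] += 1
            pd, ce = zone_metrics(states, labels, zone_sites, zone_of, n_zones,
                                  lbl_stamp, ic[I_STAMP])
            ic[I_PD] = pd
            ic[I_CE] = ce
            p = (n_zones - pd + ce - 1.0) / (n_zones + cells_initial)
            if p < 0.0:
                p = 0.0
            if p > 1.0:
                # component splits can push cells_effective past cells_initial
                p = 1.0
            fc[F_P_RANDOM] = p
            if p == 0.0 and ce >= 1:
                ic[I_PHASE] = PHASE_SHRINKING
                ic[I_SWITCH] = it
                ic[I_QUIET] = 0
                fc[F_P_RANDOM] = 0.0

        if ic[I_PHASE] == PHASE_FORAGING:
            u = rand_unit(rng)
            if u < fc[F_P_RANDOM]:
                nc = collect_eligible_gated(states, obstacle, nbr, s_max,
                                            labels, comp_cyto, cand)
            else:
                nc = collect_eligible_gated_subset(states, obstacle, nbr, s_max,
                                                   labels, comp_cyto, zone_sites, cand)
                if nc == 0:
                    nc = collect_eligible_gated(states, obstacle, nbr, s_max,
                                                labels, comp_cyto, cand)
            if nc > 0:
                t = cand[rand_below(rng, nc)]
                delta = bubble_event(states, origin, obstacle, nbr, t, True,
                                     n_swaps, membrane_budget, policy, leak,
                                     rng, touched, protected)
                if delta != 0:
                    ic[I_FORAGE_AREA_CHANGES] += 1
                ic[I_AREA] += delta
                ic[I_DIRTY] = 1
            else:
                # nothing is eligible anywhere: foraging can never act again
                ic[I_NOOPS] += 1
                if allow_fastforward:
                    den = ic[I_NCOMP] if ic[I_NCOMP] > 0 else 1
                    remaining = cap - it - 1
                    fc[F_TRUE_ITERS] += (1.0 + remaining) / den
                    ic[I_NOOPS] += remaining
                    ic[I_ITER] = cap
                    ic[I_TERM] = TERM_CAP
                    break
            den = ic[I_NCOMP] if ic[I_NCOMP] > 0 else 1
            fc[F_TRUE_ITERS] += 1.0 / den
        else:
            # shrinking: an eroding bubble event at a uniform eligible
            # stimulus among all zone sites; when no zone offers a stimulus,
            # remove one piece of interior zone cytoplasm ("creating viable
            # stimulus points"); when zones offer neither, the run is frozen
            if ic[I_DIRTY] == 1:
                ic[I_NCOMP] = label_components(states, nbr, labels, queue)
                mark_cyto_components(states, labels, comp_cyto, ic[I_NCOMP])
                ic[I_DRAIN_OK] = drain_possible(states, nbr, zone_sites, protected,
                                                visited, queue)
                ic[I_DIRTY] = 0
            area_before = ic[I_AREA]
            nc = 0
            if ic[I_DRAIN_OK] == 1:
                nc = collect_eligible_subset(states, obstacle, nbr, s_max,
                                             zone_sites, cand)
            if nc > 0:
                t = cand[rand_below(rng, nc)]
                delta = bubble_event(states, origin, obstacle, nbr, t, False,
                                     n_swaps, membrane_budget, policy, leak,
                                     rng, touched, protected)
                ic[I_SHRINK_ACTIONS] += 1
                if delta == -1:
                    ic[I_SHRINK_DECREMENTS] += 1
                else:
                    ic[I_SHRINK_REJECTED] += 1
                ic[I_AREA] += delta
                ic[I_DIRTY] = 1
            else:
                # remove one piece of interior zone cytoplasm, but only where
                # the removal provably cannot split the organism (checked by
                # trial relabeling); with no splittable-free candidate the
                # iteration is a no-op and the zone stays buried
                t = -1
                nc = collect_state_in_subset(states, zone_sites, 1, cand)
                if nc > 0:
                    ncomp0 = ic[I_NCOMP]
                    ntry = nc
                    while ntry > 0:
                        pick = rand_below(rng, ntry)
                        c2 = cand[pick]
                        st_save = states[c2]
                        or_save = origin[c2]
                        states[c2] = 0
                        origin[c2] = 0
                        if label_components(states, nbr, labels, queue) > ncomp0:
                            states[c2] = st_save
                            origin[c2] = or_save
                            cand[pick] = cand[ntry - 1]
                            ntry -= 1
                        else:
                            t = c2
                            break
                    if t < 0:
                        # trial labelings left `labels` stale; recompute lazily
                        ic[I_DIRTY] = 1
                if t >= 0:
                    touched[0] = t
                    repair_touched(states, nbr, touched, 1)
                    ic[I_SHRINK_ACTIONS] += 1
                    ic[I_SHRINK_DECREMENTS] += 1
                    ic[I_AREA] -= 1
                    ic[I_DIRTY] = 1
                else:
                    # the zones can trigger nothing: no stimulus can drain
                    # material and no zone cytoplasm can be removed without
                    # splitting; without intervention nothing can ever
                    # change again
                    if ic[I_DIRTY] == 1:
                        ic[I_NCOMP] = label_components(states, nbr, labels, queue)
                        mark_cyto_components(states, labels, comp_cyto, ic[I_NCOMP])
                        ic[I_DRAIN_OK] = drain_possible(states, nbr, zone_sites,
                                                        protected, visited, queue)
                        ic[I_DIRTY] = 0
                    cut = -1
                    if enforce_tree:
                        if pocket_loops(states, nbr, M, bounded, zone_sites,
                                        labels, labels0, queue, visited) == 1:
                            # shrinkage continues against the loops the flood
                            # fill found: open an enclosed pocket of a
                            # solution component by removing one border site,
                            # accepting only cuts that leave the component
                            # count unchanged (a ring loses a site, nothing
                            # is severed)
                            refresh_pocket_mask(states, nbr, M, bounded, special,
                                                labels0, queue, visited)
                            ic[I_STAMP] += 1
                            for kk in range(zone_sites.shape[0]):
                                zi = zone_sites[kk]
                                if states[zi] > 0:
                                    lbl_stamp[labels[zi]] = ic[I_STAMP]
                            ncut = 0
                            for i2 in range(states.shape[0]):
                                if (special[i2] == 1 and protected[i2] == 0
                                        and lbl_stamp[labels[i2]] == ic[I_STAMP]):
                                    cand[ncut] = i2
                                    ncut += 1
                            ncomp0 = ic[I_NCOMP]
                            while ncut > 0:
                                pick = rand_below(rng, ncut)
                                c2 = cand[pick]
                                st_save = states[c2]
                                or_save = origin[c2]
                                states[c2] = 0
                                origin[c2] = 0
                                if label_components(states, nbr, labels, queue) > ncomp0:
                                    states[c2] = st_save
                                    origin[c2] = or_save
                                    cand[pick] = cand[ncut - 1]
                                    ncut -= 1
                                else:
                                    cut = c2
                                    break
                    if cut >= 0:
                        touched[0] = cut
                        repair_touched(states, nbr, touched, 1)
                        ic[I_SHRINK_ACTIONS] += 1
                        ic[I_SHRINK_DECREMENTS] += 1
                        ic[I_AREA] -= 1
                        ic[I_DIRTY] = 1
                    else:
                        ic[I_NOOPS] += 1
                        if allow_fastforward:
                            den = ic[I_NCOMP] if ic[I_NCOMP] > 0 else 1
                            stuck = False
                            if enforce_tree:
                                if pocket_loops(states, nbr, M, bounded, zone_sites,
                                                labels, labels0, queue, visited) == 1:
                                    stuck = True
                            if stuck:
                                # loops remain but no cut can open them
                                # without splitting the network: run out the
                                # iteration budget
                                remaining = cap - it - 1
                                fc[F_TRUE_ITERS] += (1.0 + remaining) / den
                                ic[I_NOOPS] += remaining
                                ic[I_QUIET] += 1 + remaining
                                ic[I_ITER] = cap
                                ic[I_TERM] = TERM_CAP
                                break
                            need = threshold + 1 - ic[I_QUIET]
                            if need < 1:
                                need = 1
                            remaining = cap - it
                            k = need if need < remaining else remaining
                            fc[F_TRUE_ITERS] += k / den
                            ic[I_NOOPS] += k - 1
                            ic[I_QUIET] += k
                            ic[I_ITER] = it + k
                            ic[I_TERM] = TERM_NO_CHANGE if ic[I_QUIET] > threshold else TERM_CAP
                            break
            if ic[I_AREA] != area_before:
                ic[I_QUIET] = 0
            else:
                ic[I_QUIET] += 1
            den = ic[I_NCOMP] if ic[I_NCOMP] > 0 else 1
            fc[F_TRUE_ITERS] += 1.0 / den
            if ic[I_QUIET] > threshold:
                ok = True
                if enforce_tree:
                    if pocket_loops(states, nbr, M, bounded, zone_sites,
                                    labels, labels0, queue, visited) == 1:
                        ok = False
                if ok:
                    ic[I_ITER] = it + 1
                    ic[I_TERM] = TERM_NO_CHANGE
                    break

        if check_constraints:
            ic[I_VIOL] += count_violations(states, nbr)

        ic[I_ITER] = it + 1
        it_done += 1
        if trace_every > 0 and ic[I_ITER] % trace_every == 0:
            trace[n_trace, 0] = ic[I_ITER]
            trace[n_trace, 1] = ic[I_AREA]
            trace[n_trace, 2] = ic[I_PD]
            trace[n_trace, 3] = ic[I_CE]
            trace[n_trace, 4] = fc[F_P_RANDOM]
            trace[n_trace, 5] = ic[I_PHASE]
            n_trace += 1
    return n_trace
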
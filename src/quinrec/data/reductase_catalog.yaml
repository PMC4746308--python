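# Default catalog of quinone-dependent reductases for electron acceptors.
#
# Each entry names the quinone-interacting membrane-subunit gene families
# required to count the reductase as present in a genome, and the quinones
# the complex can draw electrons from.  Subunit labels are editable
# placeholders: the agreement statistics downstream are catalog-agnostic,
# and real analyses should substitute curated family labels.
#
# Compatibility defaults: the aerobic Cyo complex is UQ-specific; reductases
# for the strictly anaerobic acceptors (tetrathionate, thiosulfate, sulfite,
# polysulfide, fumarate, TMAO, DMSO, selenate, arsenate) pair with MK; the
# remainder are treated as promiscuous.
Cyo: {acceptor: oxygen, subunits: [cyoQ], quinones: [UQ]}
Qox: {acceptor: oxygen, subunits: [qoxQ], quinones: [UQ, MK, DMK]}
Cyd: {acceptor: oxygen, subunits: [cydQ], quinones: [UQ, MK, DMK]}
Nar: {acceptor: nitrate, subunits: [narQ], quinones: [UQ, MK, DMK]}
Nap: {acceptor: nitrate, subunits: [napQ], quinones: [UQ, MK, DMK]}
Nrf: {acceptor: nitrite, subunits: [nrfQ], quinones: [UQ, MK, DMK]}
Ttr: {acceptor: tetrathionate, subunits: [ttrQ], quinones: [MK]}
Phs: {acceptor: thiosulfate, subunits: [phsQ], quinones: [MK]}
Tsr: {acceptor: thiosulfate, subunits: [tsrQ], quinones: [MK]}
Dsr: {acceptor: sulfite, subunits: [dsrQ], quinones: [MK]}
Psr: {acceptor: polysulfide, subunits: [psrQ], quinones: [MK]}
Tor: {acceptor: trimethylamine N-oxide, subunits: [torQ], quinones: [MK]}
Dms: {acceptor: dimethyl sulfoxide, subunits: [dmsQ], quinones: [MK]}
Ynf: {acceptor: selenate, subunits: [ynfQ], quinones: [MK]}
YnfX: {acceptor: unknown, subunits: [ynfXQ], quinones: [MK]}
Frd: {acceptor: fumarate, subunits: [frdQ], quinones: [MK]}
Arx: {acceptor: arsenate, subunits: [arxQ], quinones: [MK]}
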
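table	study	raw_mirnas	tokens
5	B80	let-7d-5p, -7g-5p miR-15b-5p, -142-3p, -191-5p,-301a-3p,-545-3p	let-7d-5p;let-7g-5p;mir-15b-5p;mir-142-3p;mir-191-5p;mir-301a-3p;mir-545-3p
5	B81	miR-9, -29a, -29b, -101, -125b, -181c	mir-9;mir-29a;mir-29b;mir-101;mir-125b;mir-181c
5	B82	miR-9, -181c, -30c, -148b, -20b let-7i	mir-9;mir-181c;mir-30c;mir-148b;mir-20b;let-7i
5	B83	miR-29a, -29b,-338-3p	mir-29a;mir-29b;mir-338-3p
5	B73	let-7b, -7c, -7d,-7i, miR-103, -124a, -125a, -125b, -132, -134, -181a, -26a, -26b, -27a, -27b,-29a -29c, -204, -30a-5p, -7, -9	let-7b;let-7c;let-7d;let-7i;mir-103;mir-124a;mir-125a;mir-125b;mir-132;mir-134;mir-181a;mir-26a;mir-26b;mir-27a;mir-27b;mir-29a;mir-29c;mir-204;mir-30a-5p;mir-7;mir-9
5	B84	novel miR-36 miR-98-5p, -885-5p, -485-5p,-483-3p,-342-3p, -3158-3p,-30e-5p, -27a-3p, -26b-3p, -191-5p, -151b, let-7g-5p,-7d-5p	mir-36;mir-98-5p;mir-885-5p;mir-485-5p;mir-483-3p;mir-342-3p;mir-3158-3p;mir-30e-5p;mir-27a-3p;mir-26b-3p;mir-191-5p;mir-151b;let-7g-5p;let-7d-5p
5	B85	miR-26b-3p, -125b -223, -23a	mir-26b-3p;mir-125b;mir-223;mir-23a
5	B74	miR-338-3p, -219-2-3p, -20a,-17, -106a, -19a, -584, -338-5p, -219-5p, -32, -34c-5p, -16, -151-5p, -181a, -181b, -485-3p, -129-5p, -143, -34a, -124, -149,-136, -138, -145, -129-3p, -381,-128, -432, -378, -29b	mir-338-3p;mir-219-2-3p;mir-20a;mir-17;mir-106a;mir-19a;mir-584;mir-338-5p;mir-219-5p;mir-32;mir-34c-5p;mir-16;mir-151-5p;mir-181a;mir-181b;mir-485-3p;mir-129-5p;mir-143;mir-34a;mir-124;mir-149;mir-136;mir-138;mir-145;mir-129-3p;mir-381;mir-128;mir-432;mir-378;mir-29b
5	B86	miR-9, -125b, -132, -146a, -18	mir-9;mir-125b;mir-132;mir-146a;mir-18
5	B87	hmiR-26a-5p, -181c-3p, 126-5p, -22-3p, 148b-5p, -106b-3p, -6119-5p, -1246, -660-5p	hmir-26a-5p;hmir-181c-3p;hmir-126-5p;hmir-22-3p;hmir-148b-5p;hmir-106b-3p;hmir-6119-5p;hmir-1246;hmir-660-5p
5	B88	miR-9-5p, -106a-5p, -106b-5p, -107	mir-9-5p;mir-106a-5p;mir-106b-5p;mir-107
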
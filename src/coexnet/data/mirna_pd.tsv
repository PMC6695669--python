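table	study	raw_mirnas	tokens
6	B89	miR-34b, miR-34c	mir-34b;mir-34c
6	B90	miR-335.-374a, -199a-3p, -199b-3p, -126, -151-3p, -199a-5p, -151-5p, -29b, -147, -28-5p, -30b, -374b, -19b, -30c, -29c, -301a, -26a	mir-335;mir-374a;mir-199a-3p;mir-199b-3p;mir-126;mir-151-3p;mir-199a-5p;mir-151-5p;mir-29b;mir-147;mir-28-5p;mir-30b;mir-374b;mir-19b;mir-30c;mir-29c;mir-301a;mir-26a
6	B75	miR-132-5p, 19a-3p, -485-5p, -127-3p, -128, -409-3p, -433 -370, -431-3p, -873-3p, -121-3p, -10a, -1224-5p, -4448. miR-388-3p, -16-2-3p, -1294 -30e-3p, -30a-3p	mir-132-5p;mir-19a-3p;mir-485-5p;mir-127-3p;mir-128;mir-409-3p;mir-433;mir-370;mir-431-3p;mir-873-3p;mir-121-3p;mir-10a;mir-1224-5p;mir-4448;mir-388-3p;mir-16-2-3p;mir-1294;mir-30e-3p;mir-30a-3p
6	B91	miR-10b-5p	mir-10b-5p
6	B92	miR-29c,-146a, -214, and -22	mir-29c;mir-146a;mir-214;mir-22
6	B93	miR-24, -30c, -148b, -223, -324-3p	mir-24;mir-30c;mir-148b;mir-223;mir-324-3p
6	B94	miR-29c, -19b, -92a, -16, -100 -21, 29a, -451, -19a, -181a, -484 -134, -532-5p, -223	mir-29c;mir-19b;mir-92a;mir-16;mir-100;mir-21;mir-29a;mir-451;mir-19a;mir-181a;mir-484;mir-134;mir-532-5p;mir-223
6	B95	miR-1,-103a, -22, -29, -30b, -19-2,-26a, -331-5p, -153, -374 -132-5p, -119a, -485-5p, -127-3p, -151, -28, -301a, -873-3p, -136-3p -19b-3p, 10a-5p, -29c, let-7g-3p	mir-1;mir-103a;mir-22;mir-29;mir-30b;mir-19-2;mir-26a;mir-331-5p;mir-153;mir-374;mir-132-5p;mir-119a;mir-485-5p;mir-127-3p;mir-151;mir-28;mir-301a;mir-873-3p;mir-136-3p;mir-19b-3p;mir-10a-5p;mir-29c;let-7g-3p
6	B96	miR-27a3p, -125a-5p,-151a-3p, -423-5p let-7f-5p	mir-27a3p;mir-125a-5p;mir-151a-3p;mir-423-5p;let-7f-5p
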
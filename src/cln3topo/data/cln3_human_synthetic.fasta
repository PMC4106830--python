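>CLN3_HUMAN_synthetic reconstruction of human battenin (CLN3), 438 aa; insertion-site flanking tripeptides and N71/N85 sequons verified
MGGCAGSRRRFSDSEGEETVPEPRLPLLDHQGAHWKNAVGFWLLGLCNNFSYVVMLSAAH
DILSHKRTSGNQSHVDPGPTPAPHNSSSRFDCNSVSTAAVLLADILPTLVIKLLAPLGLH
LLPYSPRVLVSGICAAGSFVLVAFSHSVGTSLCGVVFASISSGLGEVTFLSLTAFYPRAV
ISWWSSGTGGAGLLGALSYLGLTQAGLSPQQTLLSMLGIPALLLASYFLLLTSPEAQDPG
GEEEAESAARQPLIRTEAPESKPGSSSSLSLRERWTVFKGLLWYIVPLVVVYFAEYFINQ
GLFELLFFWNTSLSHAQQYRWYQMLYQAGVFASRSSLRCCRIRFTWALALLQCLNLVFLL
ADVWFGFLPSIYLVFLIILYEGLLGGAAYVNTFHNIALETSDEHREFAMAATCISDTLGI
SLSGLLALPLHDFLCQLS
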
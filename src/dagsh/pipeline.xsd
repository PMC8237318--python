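<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="unqualified">

  <xs:simpleType name="identifier">
    <xs:restriction base="xs:string">
      <xs:pattern value="[A-Za-z_][A-Za-z0-9_]*"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="sourceKind">
    <xs:restriction base="xs:string">
      <xs:enumeration value="list"/>
      <xs:enumeration value="range"/>
      <xs:enumeration value="files_in_dir"/>
      <xs:enumeration value="param_values"/>
      <xs:enumeration value="command"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:complexType name="paramType">
    <xs:simpleContent>
      <xs:extension base="xs:string">
        <xs:attribute name="name" type="identifier" use="required"/>
        <xs:attribute name="global" type="xs:boolean" default="false"/>
        <xs:attribute name="defaultValue" type="xs:string"/>
      </xs:extension>
    </xs:simpleContent>
  </xs:complexType>

  <xs:complexType name="taskType">
    <xs:simpleContent>
      <xs:extension base="xs:string">
        <xs:attribute name="id" type="identifier" use="required"/>
        <xs:attribute name="params" type="xs:string"/>
        <xs:attribute name="after" type="xs:string"/>
        <xs:attribute name="interpreter" type="xs:string"/>
        <xs:attribute name="if" type="xs:string"/>
      </xs:extension>
    </xs:simpleContent>
  </xs:complexType>

  <xs:complexType name="foreachType">
    <xs:simpleContent>
      <xs:extension base="xs:string">
        <xs:attribute name="id" type="identifier" use="required"/>
        <xs:attribute name="params" type="xs:string"/>
        <xs:attribute name="after" type="xs:string"/>
        <xs:attribute name="interpreter" type="xs:string"/>
        <xs:attribute name="if" type="xs:string"/>
        <xs:attribute name="of" type="sourceKind" use="required"/>
        <xs:attribute name="in" type="xs:string" use="required"/>
        <xs:attribute name="as" type="identifier" use="required"/>
      </xs:extension>
    </xs:simpleContent>
  </xs:complexType>

  <xs:complexType name="taskDescriptionType">
    <xs:simpleContent>
      <xs:extension base="xs:string">
        <xs:attribute name="id" type="identifier" use="required"/>
      </xs:extension>
    </xs:simpleContent>
  </xs:complexType>

  <xs:element name="pipeline">
    <xs:complexType>
      <xs:all>
        <xs:element name="params" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="param" type="paramType" minOccurs="0" maxOccurs="unbounded"/>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="tasks" minOccurs="0">
          <xs:complexType>
            <xs:choice minOccurs="0" maxOccurs="unbounded">
              <xs:element name="task" type="taskType"/>
              <xs:element name="foreach" type="foreachType"/>
            </xs:choice>
          </xs:complexType>
        </xs:element>
        <xs:element name="metadata" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="task-description" type="taskDescriptionType" minOccurs="0" maxOccurs="unbounded"/>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
      </xs:all>
      <xs:attribute name="version" type="xs:string"/>
    </xs:complexType>
  </xs:element>

</xs:schema>
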